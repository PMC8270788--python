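"""A/B compartment scores by eigenvector reference and projection.

A reference per-bin vector comes from the leading eigenvector of the
correlation matrix of an observed/expected map, is oriented so that
positive values track an active histone mark, and is projected onto the
O/E maps of other stages; projected scores are mean-centered, scaled to
[-1, 1] and signed into A (positive) and B (negative) states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .matrix_core import ContactMatrix

__all__ = [
    "CompartmentTrack",
    "reference_compartment_vector",
    "orient_by_signal",
    "project_compartment_score",
    "normalize_scores",
    "switch_tracking",
]

MIN_UNMASKED_BINS = 10


@dataclass
class CompartmentTrack:
    """Per-bin compartment score in [-1, 1] with A/B sign labels."""

    scores: np.ndarray  # NaN where masked
    bin_size: int
    stage: str = ""
    orientation_source: str = ""

    @property
    def labels(self) -> np.ndarray:
        """'A' where score > 0, 'B' where score < 0, '' elsewhere."""
        out = np.full(self.scores.shape, "", dtype=object)
        out[np.nan_to_num(self.scores) > 0] = "A"
        out[np.nan_to_num(self.scores) < 0] = "B"
        out[~np.isfinite(self.scores)] = ""
        return out


def _oe_dense(oe_matrix: ContactMatrix) -> np.ndarray:
    dense = oe_matrix.to_dense()
    dense = dense.astype(float)
    dense[~oe_matrix.mask, :] = np.nan
    dense[:, ~oe_matrix.mask] = np.nan
    return dense


def reference_compartment_vector(oe_matrix: ContactMatrix) -> np.ndarray:
    """Leading eigenvector of the O/E column correlation matrix.

    The sign is arbitrary at this stage; masked or zero-variance bins
    come back NaN.
    """
    dense = _oe_dense(oe_matrix)
    n = dense.shape[0]
    unmasked = oe_matrix.mask.copy()
    sub = dense[np.ix_(unmasked, unmasked)]
    var_ok = np.nanstd(sub, axis=0) > 0
    idx = np.where(unmasked)[0][var_ok]
    if idx.size < MIN_UNMASKED_BINS:
        raise ValueError(f"only {idx.size} usable bins; need {MIN_UNMASKED_BINS}")
    sub = dense[np.ix_(idx, idx)]
    corr = np.corrcoef(sub, rowvar=False)
    corr = np.nan_to_num(corr)
    evals, evecs = np.linalg.eigh(corr)
    lead = evecs[:, -1]
    out = np.full(n, np.nan)
    out[idx] = lead
    return out


def orient_by_signal(raw_vector: np.ndarray, active_mark_track: np.ndarray) -> np.ndarray:
    """Flip the vector sign so it correlates positively with active marks."""
    v = np.asarray(raw_vector, dtype=float)
    m = np.asarray(active_mark_track, dtype=float)
    ok = np.isfinite(v) & np.isfinite(m)
    if ok.sum() < 2 or np.std(m[ok]) == 0:
        raise ValueError("active-mark track has no variance; orientation unresolved")
    if np.std(v[ok]) == 0:
        raise ValueError("reference vector has no variance")
    r = np.corrcoef(v[ok], m[ok])[0, 1]
    return -v if r < 0 else v


def project_compartment_score(
    oe_matrix_stage: ContactMatrix, reference_vector: np.ndarray
) -> np.ndarray:
    """Matrix-vector projection: score_i = sum_j OE_ij * ref_j."""
    ref = np.asarray(reference_vector, dtype=float)
    if ref.shape[0] != oe_matrix_stage.n_bins:
        raise ValueError("reference vector is on a different bin grid")
    dense = _oe_dense(oe_matrix_stage)
    refz = np.where(np.isfinite(ref), ref, 0.0)
    densez = np.nan_to_num(dense)
    scores = densez @ refz
    scores[~oe_matrix_stage.mask] = np.nan
    return scores


def normalize_scores(
    raw_scores: np.ndarray,
    bin_size: int,
    stage: str = "",
    orientation_source: str = "",
) -> CompartmentTrack:
    """Mean-center over defined bins and scale by the max absolute value.

    Zero stays the A/B boundary; when all scores are equal the track is
    all zeros with no labels.
    """
    s = np.asarray(raw_scores, dtype=float).copy()
    ok = np.isfinite(s)
    if not ok.any():
        raise ValueError("no defined score")
    s[ok] -= s[ok].mean()
    peak = np.abs(s[ok]).max()
    if peak == 0:
        warnings.warn("all compartment scores equal; no A/B labels")
    else:
        s[ok] /= peak
    return CompartmentTrack(s, bin_size, stage=stage, orientation_source=orientation_source)


def switch_tracking(tracks: Sequence[CompartmentTrack]) -> pd.DataFrame:
    """Per-transition counts of A->B, B->A, stable-A and stable-B bins.

    Bins masked (or unlabeled) in either track of a pair are excluded.
    Returns a frame with one row per consecutive pair.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    n = tracks[0].scores.shape[0]
    for t in tracks:
        if t.scores.shape[0] != n:
            raise ValueError("tracks are on different grids")
    rows = []
    for k in range(len(tracks) - 1):
        a, b = tracks[k].labels, tracks[k + 1].labels
        ok = (a != "") & (b != "")
        counts = {
            "stable_A": int(np.sum(ok & (a == "A") & (b == "A"))),
            "stable_B": int(np.sum(ok & (a == "B") & (b == "B"))),
            "A_to_B": int(np.sum(ok & (a == "A") & (b == "B"))),
            "B_to_A": int(np.sum(ok & (a == "B") & (b == "A"))),
        }
        total = sum(counts.values())
        switch = counts["A_to_B"] + counts["B_to_A"]
        rows.append(
            {
                "from": tracks[k].stage or str(k),
                "to": tracks[k + 1].stage or str(k + 1),
                **counts,
                "n_bins": total,
                "switch_fraction": switch / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)
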