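"""Border DI vectors, k-means asymmetry classes, DI bias and profiles.

Each domain contributes a feature row of directionality-index values
around its 5' and 3' borders; k-means over these rows separates domains
into asymmetry classes, the DI-bias statistic quantifies per-domain
border asymmetry, and signal profiles compare coverage tracks across
border groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .domain_metrics import DITrack
from .tad_consensus import Domain, DomainSet

__all__ = [
    "BorderDIMatrix",
    "ClusterAssignment",
    "border_di_vectors",
    "kmeans_border_clusters",
    "di_bias",
    "subcluster_by_di_strength",
    "profile_signal_over_borders",
]

DEFAULT_FLANK_BINS = 5
DEFAULT_K = 3
DEFAULT_N_SUB = 5
DI_BIAS_WINDOW_BINS = 3


@dataclass
class BorderDIMatrix:
    """One feature row per domain: DI around the 5' then the 3' border.

    ``features`` has ``4 * flank_bins`` columns (``+/-flank`` at each
    border); rows whose windows leave the defined DI range are zeroed
    and flagged in ``masked``.
    """

    features: np.ndarray
    masked: np.ndarray
    flank_bins: int
    domain_index: np.ndarray  # positions into the originating DomainSet


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..k per row; 0 for masked rows
    centroids: np.ndarray
    seed: int
    inertia: float
    degenerate: bool = False
    subclusters: Dict[int, str] = field(default_factory=dict)


def border_di_vectors(
    domains: DomainSet,
    di_track: DITrack,
    flank_bins: int = DEFAULT_FLANK_BINS,
) -> BorderDIMatrix:
    """Assemble per-domain DI windows around both borders."""
    if flank_bins < 1:
        raise ValueError("flank_bins must be >= 1")
    di = di_track.values
    n = di.shape[0]
    bs = domains.bin_size
    rows, masked = [], []
    for d in domains:
        b5, b3 = d.bins(bs)
        idx5 = np.arange(b5 - flank_bins, b5 + flank_bins)
        idx3 = np.arange(b3 - flank_bins, b3 + flank_bins)
        idx = np.concatenate([idx5, idx3])
        if idx.min() < 0 or idx.max() >= n:
            rows.append(np.zeros(4 * flank_bins))
            masked.append(True)
            continue
        row = di[idx]
        bad = ~np.isfinite(row)
        row = np.where(bad, 0.0, row)
        rows.append(row)
        masked.append(bool(bad.any()))
    return BorderDIMatrix(
        features=np.asarray(rows, dtype=float),
        masked=np.asarray(masked, dtype=bool),
        flank_bins=flank_bins,
        domain_index=np.arange(len(domains)),
    )


def _canonical_order(centroids: np.ndarray, flank_bins: int) -> np.ndarray:
    """Order clusters 5'-dominant, intermediate, 3'-dominant."""
    half = 2 * flank_bins
    asym = np.abs(centroids[:, :half]).mean(axis=1) - np.abs(
        centroids[:, half:]
    ).mean(axis=1)
    order = np.argsort(-asym)  # most 5'-dominant first
    if len(order) == 3:
        # keep cluster 2 as the intermediate class
        return order[[0, 1, 2]]
    return order


def kmeans_border_clusters(
    features: BorderDIMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """Lloyd k-means over unmasked rows, canonically relabeled.

    Cluster 1 holds the 5'-dominant centroid (largest excess of mean
    |DI| at the 5' border over the 3' border), cluster ``k`` the
    3'-dominant one; labels for masked rows are 0.
    """
    keep = ~features.masked
    x = features.features[keep]
    if x.shape[0] < k:
        raise ValueError(f"need at least {k} unmasked rows, got {x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)
    order = _canonical_order(km.cluster_centers_, features.flank_bins)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = np.zeros(features.features.shape[0], dtype=int)
    labels[keep] = relabel[raw]
    degenerate = len(np.unique(raw)) < k or np.allclose(
        km.cluster_centers_.std(axis=0), 0
    )
    return ClusterAssignment(
        labels=labels,
        centroids=km.cluster_centers_[order],
        seed=seed,
        inertia=float(km.inertia_),
        degenerate=bool(degenerate),
    )


def di_bias(
    domain: Domain,
    di_track: DITrack,
    bin_size: int,
    window_bins: int = DI_BIAS_WINDOW_BINS,
    inset_fraction: float = 0.0,
) -> Optional[float]:
    """log2 of |mean DI just inside the 5' border / just inside the 3' border|.

    The 5' window covers ``window_bins`` bins to the right of the 5'
    border, the 3' window the bins to the left of the 3' border;
    ``inset_fraction`` shifts both windows fractionally into the domain
    interior. None when either window is undefined or averages to zero.
    """
    di = di_track.values
    b5, b3 = domain.bins(bin_size)
    shift = int(round(inset_fraction * (b3 - b5)))
    w5 = di[b5 + shift : b5 + shift + window_bins]
    w3 = di[b3 - shift - window_bins : b3 - shift]
    if w5.shape[0] < window_bins or w3.shape[0] < window_bins:
        return None
    if not (np.isfinite(w5).all() and np.isfinite(w3).all()):
        return None
    m5, m3 = w5.mean(), w3.mean()
    if m5 == 0 or m3 == 0:
        return None
    return float(np.log2(abs(m5 / m3)))


def subcluster_by_di_strength(
    members: Sequence[Domain],
    n_sub: int = DEFAULT_N_SUB,
) -> List[str]:
    """Rank members by DI bias and split into near-equal contiguous groups.

    Group sizes differ by at most one (larger groups first); ties in DI
    bias break by domain start coordinate. Labels are '2a'..'2e' style.
    """
    if len(members) < n_sub:
        raise ValueError(f"need at least {n_sub} members, got {len(members)}")
    biases = []
    for d in members:
        if d.di_bias is None:
            raise ValueError("all members need a di_bias value")
        biases.append(d.di_bias)
    order = sorted(
        range(len(members)), key=lambda i: (-biases[i], members[i].start)
    )
    sizes = [len(members) // n_sub + (1 if r < len(members) % n_sub else 0) for r in range(n_sub)]
    labels = [""] * len(members)
    pos = 0
    for g, size in enumerate(sizes):
        tag = "2" + chr(ord("a") + g)
        for i in order[pos : pos + size]:
            labels[i] = tag
        pos += size
    return labels


def profile_signal_over_borders(
    track: np.ndarray,
    domains: DomainSet,
    flank_bins: int = DEFAULT_FLANK_BINS,
    labels: Optional[Sequence] = None,
    groups: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Mean +/- s.e.m. of a per-bin track across grouped domain borders.

    Returns a tidy frame with columns (group, side, offset, mean, sem,
    n); 5' and 3' borders are profiled separately. Empty groups produce
    no rows (with a warning).
    """
    bs = domains.bin_size
    if labels is None:
        labels = ["all"] * len(domains)
    labels = list(labels)
    n = track.shape[0]
    records = []
    if groups is None:
        groups = sorted(set(labels), key=str)
    for group in groups:
        idx = [i for i, g in enumerate(labels) if g == group]
        if not idx:
            warnings.warn(f"empty group {group!r}")
            continue
        for side in ("5p", "3p"):
            for off in range(-flank_bins, flank_bins + 1):
                vals = []
                for i in idx:
                    b5, b3 = domains[i].bins(bs)
                    b = (b5 if side == "5p" else b3) + off
                    if 0 <= b < n and np.isfinite(track[b]):
                        vals.append(track[b])
                if not vals:
                    continue
                arr = np.asarray(vals)
                sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else np.nan
                records.append(
                    {
                        "group": group,
                        "side": side,
                        "offset": off,
                        "mean": float(arr.mean()),
                        "sem": sem,
                        "n": arr.size,
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["group", "side", "offset", "mean", "sem", "n"]
    )
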