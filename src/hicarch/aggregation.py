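"""Rescaled aggregate-domain maps, ratio maps, and track PCA.

Each domain window (domain plus flanks) is resampled to a common grid by
area-weighted averaging, averaged across domains, and divided by its
grand mean; ratio maps compare conditions pixel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import PCA

from .matrix_core import ContactMatrix
from .tad_consensus import DomainSet

__all__ = [
    "AggregateMap",
    "aggregate_domains",
    "ratio_aggregate",
    "aggregate_on_reference_set",
    "pca_tracks",
]

DEFAULT_GRID = 90
DEFAULT_FLANK_FRACTION = 0.5


@dataclass
class AggregateMap:
    values: np.ndarray  # grid x grid, grand mean 1 after normalization
    n_domains: int
    grid: int
    flank_fraction: float
    normalization_tag: str


def _resample_weights(w: int, g: int) -> np.ndarray:
    """(g, w) area-overlap weights mapping w source bins onto g cells.

    Each row is normalized to sum 1, so the resampled value is the
    area-weighted mean of the overlapped source bins.
    """
    edges = np.linspace(0.0, w, g + 1)
    mat = np.zeros((g, w))
    for t in range(g):
        lo, hi = edges[t], edges[t + 1]
        b0, b1 = int(np.floor(lo)), int(np.ceil(hi))
        for b in range(b0, min(b1, w)):
            mat[t, b] = min(hi, b + 1) - max(lo, b)
    return mat / mat.sum(axis=1, keepdims=True)


def _resample_window(window: np.ndarray, grid: int) -> np.ndarray:
    """Area-weighted resample of a (possibly NaN-masked) square window."""
    w = window.shape[0]
    wt = _resample_weights(w, grid)
    finite = np.isfinite(window)
    filled = np.where(finite, window, 0.0)
    num = wt @ filled @ wt.T
    den = wt @ finite.astype(float) @ wt.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def aggregate_domains(
    matrix: ContactMatrix,
    domains: DomainSet,
    grid: int = DEFAULT_GRID,
    flank_fraction: float = DEFAULT_FLANK_FRACTION,
) -> AggregateMap:
    """Mean rescaled window over domains, normalized by its grand mean.

    Each window spans the domain plus ``flank_fraction`` of its length
    on both sides; bins off the chromosome (or masked) are excluded from
    every average.
    """
    if len(domains) == 0:
        raise ValueError("cannot aggregate an empty domain set")
    dense = matrix.to_dense()
    dense = dense.astype(float)
    if not matrix.mask.all():
        dense[~matrix.mask, :] = np.nan
        dense[:, ~matrix.mask] = np.nan
    n = matrix.n_bins
    bs = domains.bin_size
    acc = np.zeros((grid, grid))
    cnt = np.zeros((grid, grid))
    for d in domains:
        s, e = d.bins(bs)
        length = e - s
        flank = int(round(flank_fraction * length))
        lo, hi = s - flank, e + flank
        w = hi - lo
        window = np.full((w, w), np.nan)
        src_lo, src_hi = max(lo, 0), min(hi, n)
        window[src_lo - lo : src_hi - lo, src_lo - lo : src_hi - lo] = dense[
            src_lo:src_hi, src_lo:src_hi
        ]
        res = _resample_window(window, grid)
        ok = np.isfinite(res)
        acc[ok] += res[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_map = np.where(cnt > 0, acc / cnt, np.nan)
    grand = np.nanmean(mean_map)
    if grand > 0:
        mean_map = mean_map / grand
    return AggregateMap(
        values=mean_map,
        n_domains=len(domains),
        grid=grid,
        flank_fraction=flank_fraction,
        normalization_tag=matrix.normalization_tag,
    )


def ratio_aggregate(map_a: AggregateMap, map_b: AggregateMap) -> np.ndarray:
    """Element-wise map_a / map_b; zero denominators become NaN."""
    if map_a.grid != map_b.grid:
        raise ValueError("aggregate maps are on different grids")
    a, b = map_a.values, map_b.values
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((b != 0) & np.isfinite(b), a / b, np.nan)
    return out


def aggregate_on_reference_set(
    condition_matrix: ContactMatrix,
    control_domains: DomainSet,
    grid: int = DEFAULT_GRID,
    flank_fraction: float = DEFAULT_FLANK_FRACTION,
) -> AggregateMap:
    """Aggregate a condition matrix over the CONTROL condition's domains."""
    return aggregate_domains(condition_matrix, control_domains, grid, flank_fraction)


def pca_tracks(
    tracks: Sequence[np.ndarray],
) -> Tuple[np.ndarray, np.ndarray]:
    """PCA of per-stage tracks (DI or compartment score).

    Bins undefined in any track are masked out; returns (coordinates,
    explained-variance fractions) with one row of coordinates per track.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    x = np.vstack([np.asarray(t, dtype=float) for t in tracks])
    keep = np.isfinite(x).all(axis=0)
    if not keep.any():
        raise ValueError("no bin defined in every track")
    pca = PCA()
    coords = pca.fit_transform(x[:, keep])
    return coords, pca.explained_variance_ratio_
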