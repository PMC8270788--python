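"""Per-bin and per-domain contact scores.

Directionality index and insulation are per-bin tracks computed with a
fixed block size (default 40 bins, i.e. 400 kb at 10-kb resolution); the
diamond score and the arrowhead-style corner score are per-domain
statistics of contact enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .matrix_core import ContactMatrix

__all__ = [
    "DITrack",
    "InsulationTrack",
    "DiamondScore",
    "directionality_index",
    "insulation_score",
    "diamond_score",
    "arrowhead_corner_score",
]

DEFAULT_BLOCK_BINS = 40

#: An edge-truncated flank shorter than this fraction of the domain
#: length makes the corresponding diamond score side unusable.
MIN_FLANK_FRACTION = 0.25


@dataclass
class DITrack:
    values: np.ndarray  # NaN where undefined
    block_bins: int


@dataclass
class InsulationTrack:
    values: np.ndarray  # log2(diamond mean / chromosome mean); NaN at edges
    block_bins: int


@dataclass
class DiamondScore:
    value: Optional[float]  # None when unscorable
    middle_sum: float
    upstream_sum: float
    downstream_sum: float
    flank_used: str  # 'upstream' | 'downstream' | 'none'


def _sat(dense: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero border row/column."""
    s = np.zeros((dense.shape[0] + 1, dense.shape[1] + 1))
    s[1:, 1:] = dense.cumsum(axis=0).cumsum(axis=1)
    return s


def _rect_sum(sat: np.ndarray, r0: int, r1: int, c0: int, c1: int) -> float:
    """Sum of dense[r0:r1, c0:c1] (clipped to the matrix)."""
    n = sat.shape[0] - 1
    r0, r1 = max(r0, 0), min(r1, n)
    c0, c1 = max(c0, 0), min(c1, n)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    return float(sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0])


def directionality_index(
    matrix: ContactMatrix, block_bins: int = DEFAULT_BLOCK_BINS
) -> DITrack:
    """Chi-square-like statistic of upstream vs downstream contact preference.

    For each bin, ``A`` sums contacts to the ``block_bins`` upstream bins
    and ``B`` to the downstream bins;
    ``DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E)`` with
    ``E = (A + B) / 2``. DI is 0 when ``A == B`` and undefined (NaN)
    where ``A + B == 0``.
    """
    if block_bins < 1:
        raise ValueError("block_bins must be >= 1")
    dense = matrix.to_dense()
    n = matrix.n_bins
    sat = _sat(dense)
    out = np.full(n, np.nan)
    for i in range(n):
        a = _rect_sum(sat, i, i + 1, i - block_bins, i)
        b = _rect_sum(sat, i, i + 1, i + 1, i + block_bins + 1)
        tot = a + b
        if tot == 0 or not matrix.mask[i]:
            continue
        if a == b:
            out[i] = 0.0
            continue
        e = tot / 2.0
        out[i] = np.sign(b - a) * ((a - e) ** 2 / e + (b - e) ** 2 / e)
    return DITrack(out, block_bins)


def insulation_score(
    matrix: ContactMatrix, block_bins: int = DEFAULT_BLOCK_BINS
) -> InsulationTrack:
    """Sliding-diamond insulation, log2-normalized to the chromosome mean.

    The raw score at bin ``i`` is the mean value in the
    ``block_bins x block_bins`` square spanning
    ``[i - block_bins, i) x [i, i + block_bins)``; bins within
    ``block_bins`` of either chromosome edge are undefined.
    """
    if block_bins < 1:
        raise ValueError("block_bins must be >= 1")
    n = matrix.n_bins
    if n < 2 * block_bins:
        warnings.warn("chromosome shorter than two blocks; insulation all missing")
        return InsulationTrack(np.full(n, np.nan), block_bins)
    dense = matrix.to_dense()
    sat = _sat(dense)
    raw = np.full(n, np.nan)
    area = float(block_bins * block_bins)
    for i in range(block_bins, n - block_bins + 1):
        if not matrix.mask[i]:
            continue
        raw[i] = _rect_sum(sat, i - block_bins, i, i, i + block_bins) / area
    defined = np.isfinite(raw) & (raw > 0)
    if not defined.any():
        warnings.warn("insulation undefined everywhere")
        return InsulationTrack(np.full(n, np.nan), block_bins)
    mean_raw = raw[np.isfinite(raw)].mean()
    out = np.full(n, np.nan)
    with np.errstate(divide="ignore"):
        valid = np.isfinite(raw)
        out[valid] = np.log2(raw[valid] / mean_raw)
    out[np.isneginf(out)] = np.nan
    return InsulationTrack(out, block_bins)


def _domain_bins(matrix: ContactMatrix, start_bp: int, end_bp: int) -> Tuple[int, int]:
    bs = matrix.bin_table.bin_size
    if start_bp % bs or (end_bp % bs and end_bp != matrix.bin_table.chrom_length):
        raise ValueError("domain coordinates must lie on the bin grid")
    return start_bp // bs, -(-end_bp // bs)


def diamond_score(
    matrix: ContactMatrix,
    start_bp: int,
    end_bp: int,
    symmetric: bool = False,
) -> DiamondScore:
    """Domain-strength ratio of intra-domain to flank contact sums.

    The middle area is the full domain square of the symmetric matrix;
    the upstream (downstream) area is the equal-length flank-by-domain
    rectangle. The score is ``middle / (upstream + middle)``;
    ``symmetric=True`` computes ``middle / (upstream + downstream +
    middle)`` instead. Flanks truncated by a chromosome edge are rescaled
    by full-area/available-area; if less than 25% of the upstream flank
    is available the downstream flank is used as fallback, and the domain
    is unscorable if neither flank qualifies.
    """
    s, e = _domain_bins(matrix, start_bp, end_bp)
    n = matrix.n_bins
    length = e - s
    if length < 1 or s < 0 or e > n:
        raise ValueError("domain does not lie on the matrix")
    dense = matrix.to_dense()
    sat = _sat(dense)
    middle = _rect_sum(sat, s, e, s, e)

    def flank_sum(up: bool) -> Tuple[float, float]:
        if up:
            r0, r1 = s - length, s
            avail = min(s, length)
        else:
            r0, r1 = e, e + length
            avail = min(n - e, length)
        frac = avail / length
        if frac < MIN_FLANK_FRACTION:
            return np.nan, frac
        raw = _rect_sum(sat, r0, r1, s, e)
        return raw / frac, frac  # area-ratio edge correction

    up_sum, up_frac = flank_sum(up=True)
    down_sum, down_frac = flank_sum(up=False)

    if symmetric:
        if np.isnan(up_sum) or np.isnan(down_sum):
            return DiamondScore(None, middle, up_sum, down_sum, "none")
        denom = up_sum + down_sum + middle
        value = middle / denom if denom > 0 else None
        return DiamondScore(value, middle, up_sum, down_sum, "upstream")

    if not np.isnan(up_sum):
        flank, used = up_sum, "upstream"
    elif not np.isnan(down_sum):
        flank, used = down_sum, "downstream"
    else:
        return DiamondScore(None, middle, np.nan, np.nan, "none")
    denom = flank + middle
    if denom <= 0:
        return DiamondScore(None, middle, up_sum, down_sum, used)
    return DiamondScore(middle / denom, middle, up_sum, down_sum, used)


def arrowhead_corner_score(
    matrix: ContactMatrix,
    start_bp: int,
    end_bp: int,
    max_height: int = 20,
) -> float:
    """Corner-likelihood score from the arrowhead sign transform.

    The transform is ``T[i, i+d] = (M[i, i-d] - M[i, i+d]) /
    (M[i, i-d] + M[i, i+d])``. A genuine domain corner leaves a strongly
    negative triangle of T just inside the corner while the flanking
    triangles stay near zero, so the score is the flank mean minus the
    corner mean (higher = more corner-like). NaN if the corner region
    falls off the matrix.
    """
    s, e = _domain_bins(matrix, start_bp, end_bp)
    n = matrix.n_bins
    length = e - s
    h = min(length, max_height)
    if s - h < 0 or e + h > n or s < length - 1:
        return np.nan  # corner region or its mirror falls off the matrix
    dense = matrix.to_dense()

    def t_value(i: int, j: int) -> float:
        # requires the mirrored pixel (i, i-d) on the matrix
        d = j - i
        if d <= 0 or i - d < 0 or j >= n or i < 0:
            return np.nan
        lo, hi = dense[i, i - d], dense[i, i + d]
        tot = lo + hi
        if tot == 0:
            return 0.0
        return (lo - hi) / tot

    corner, flank = [], []
    c = e - 1  # corner pixel column
    for u in range(h):
        for v in range(h - u):
            corner.append(t_value(s + u, c - v))
            flank.append(t_value(s - 1 - u, c - v))  # upstream of 5' border
            flank.append(t_value(s + u, e + v))  # downstream of 3' border
    corner_arr = np.asarray(corner, dtype=float)
    flank_arr = np.asarray(flank, dtype=float)
    if not np.isfinite(corner_arr).any() or not np.isfinite(flank_arr).any():
        return np.nan
    return float(np.nanmean(flank_arr) - np.nanmean(corner_arr))
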