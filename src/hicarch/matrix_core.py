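"""Contact-matrix data model, triplet I/O, normalization and distance decay.

A :class:`ContactMatrix` holds a per-chromosome symmetric sparse count
matrix on a fixed bin grid. Normalization produces per-bin multiplicative
weight vectors (vanilla coverage, its square root, or full matrix
balancing by iterative proportional fitting); the distance-decay expected
profile and the observed/expected transform build on the normalized
matrix. All operations are cis (single chromosome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BinTable",
    "ContactMatrix",
    "NormalizationVector",
    "ExpectedProfile",
    "read_bin_table",
    "write_bin_table",
    "read_contact_matrix",
    "write_contact_matrix",
    "compute_normalization",
    "apply_normalization",
    "expected_by_distance",
    "observed_over_expected",
    "write_bedgraph",
    "read_bedgraph",
]

#: Bins whose marginal falls below this fraction of the median nonzero
#: marginal are masked before balancing.
COVERAGE_FLOOR_FRACTION = 0.02


@dataclass(frozen=True)
class BinTable:
    """Uniform tiling of a chromosome into fixed-size bins.

    Coordinates are 0-based half-open; ``bin_id`` is the consecutive
    integer index starting at 0.
    """

    chrom: str
    chrom_length: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_size

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.bin_size, self.chrom_length)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "bin_id": np.arange(self.n_bins),
            }
        )


def write_bin_table(bins: BinTable, path: Union[str, Path]) -> None:
    bins.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bin_table(path: Union[str, Path]) -> BinTable:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "bin_id"],
    )
    if df.empty:
        raise ValueError(f"empty bin table: {path}")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("bin table must cover a single chromosome")
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if not np.array_equal(df["bin_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("bin_id must be consecutive from 0")
    if np.any(starts[1:] != ends[:-1]) or starts[0] != 0:
        raise ValueError("bins must tile the chromosome without gaps")
    bin_size = int(ends[0] - starts[0]) if len(df) > 1 else int(ends[0])
    if len(df) > 1:
        bin_size = int(starts[1] - starts[0])
    return BinTable(chrom=str(chroms[0]), chrom_length=int(ends[-1]), bin_size=bin_size)


class ContactMatrix:
    """Symmetric per-chromosome contact matrix on a bin grid.

    Internally stored as a CSR matrix of the full symmetric form; the
    triplet representation (upper triangle, ``i <= j``) is materialized
    on demand. ``mask`` marks bins considered valid (unmasked); entries
    never carry masked bins.
    """

    def __init__(
        self,
        bin_table: BinTable,
        matrix: sp.spmatrix,
        normalization_tag: str = "raw",
        mask: Optional[np.ndarray] = None,
    ):
        n = bin_table.n_bins
        matrix = sp.csr_matrix(matrix, shape=(n, n))
        if matrix.nnz and matrix.data.min() < 0:
            raise ValueError("contact values must be non-negative")
        self.bin_table = bin_table
        self._mat = matrix
        self.normalization_tag = normalization_tag
        if mask is None:
            mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_triplets(
        cls,
        bin_table: BinTable,
        i: Iterable[int],
        j: Iterable[int],
        values: Iterable[float],
        normalization_tag: str = "raw",
    ) -> "ContactMatrix":
        i = np.asarray(list(i), dtype=np.int64)
        j = np.asarray(list(j), dtype=np.int64)
        v = np.asarray(list(values), dtype=np.float64)
        n = bin_table.n_bins
        if i.size and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise IndexError("triplet index out of bin-table range")
        if v.size and v.min() < 0:
            raise ValueError("negative contact value")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        upper = sp.coo_matrix((v, (lo, hi)), shape=(n, n)).tocsr()
        upper.sum_duplicates()
        full = upper + sp.triu(upper, k=1).T
        return cls(bin_table, full, normalization_tag=normalization_tag)

    @classmethod
    def from_dense(
        cls, bin_table: BinTable, dense: np.ndarray, normalization_tag: str = "raw"
    ) -> "ContactMatrix":
        dense = np.asarray(dense, dtype=np.float64)
        if not np.allclose(dense, dense.T):
            raise ValueError("dense matrix must be symmetric")
        return cls(bin_table, sp.csr_matrix(dense), normalization_tag=normalization_tag)

    # -- views ----------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.bin_table.n_bins

    @property
    def nnz(self) -> int:
        return sp.triu(self._mat).nnz

    def to_dense(self, fill_masked: float = 0.0) -> np.ndarray:
        """Dense symmetric array; masked rows/cols set to ``fill_masked``."""
        d = self._mat.toarray()
        if not self.mask.all():
            d[~self.mask, :] = fill_masked
            d[:, ~self.mask] = fill_masked
        return d

    def triplets(self) -> pd.DataFrame:
        """Upper-triangle triplets sorted by (i, j)."""
        upper = sp.triu(self._mat).tocoo()
        df = pd.DataFrame({"i": upper.row, "j": upper.col, "value": upper.data})
        return df.sort_values(["i", "j"], kind="mergesort").reset_index(drop=True)

    def marginals(self) -> np.ndarray:
        """Row sums of the full symmetric matrix."""
        return np.asarray(self._mat.sum(axis=1)).ravel()

    def total(self) -> float:
        """Sum over the full symmetric matrix (off-diagonal counted twice)."""
        return float(self._mat.sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.bin_table, self._mat.copy(), self.normalization_tag, self.mask.copy()
        )


def read_contact_matrix(path: Union[str, Path], bin_table: BinTable) -> ContactMatrix:
    """Read a triplet text matrix (``i<TAB>j<TAB>value``; ``#`` comments).

    Duplicate entries are summed and ``(j, i)`` is folded into ``(i, j)``
    with ``i <= j``. Indices are bin ids, validated against ``bin_table``.
    """
    n = bin_table.n_bins
    ii, jj, vv = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {line!r}")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable triplet {line!r}") from exc
            if i < 0 or j < 0 or i >= n or j >= n:
                raise IndexError(
                    f"{path}:{lineno}: bin index out of range for {n}-bin table: {line!r}"
                )
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative count: {line!r}")
            ii.append(i)
            jj.append(j)
            vv.append(v)
    return ContactMatrix.from_triplets(bin_table, ii, jj, vv)


def _format_value(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_contact_matrix(matrix: ContactMatrix, path: Union[str, Path]) -> None:
    """Write upper-triangle triplets as tab-separated text."""
    df = matrix.triplets()
    with open(path, "w") as fh:
        for i, j, v in zip(df["i"], df["j"], df["value"]):
            fh.write(f"{i}\t{j}\t{_format_value(v)}\n")


@dataclass
class NormalizationVector:
    """Per-bin multiplicative weights; NaN marks missing bins."""

    weights: np.ndarray
    method: str
    convergence_stat: float = np.nan
    converged: bool = True

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.weights)


def _coverage_mask(matrix: ContactMatrix) -> np.ndarray:
    """Valid bins: marginal at or above the coverage floor."""
    marg = matrix.marginals()
    nz = marg[marg > 0]
    if nz.size == 0:
        return np.zeros(matrix.n_bins, dtype=bool)
    floor = COVERAGE_FLOOR_FRACTION * np.median(nz)
    return (marg > 0) & (marg >= floor) & matrix.mask


def compute_normalization(
    matrix: ContactMatrix,
    method: str = "balanced",
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> NormalizationVector:
    """Compute per-bin weights for VC, VC_SQRT or full balancing.

    VC weights are ``c / rowsum``; VC_SQRT uses ``c / sqrt(rowsum)``; the
    constant ``c`` preserves the total matrix sum. Balancing iteratively
    rescales weights until the relative standard deviation of the
    weighted row sums over valid bins drops below ``tol``.
    """
    if method not in {"VC", "VC_SQRT", "balanced"}:
        raise ValueError(f"unknown normalization method: {method}")
    n = matrix.n_bins
    valid = _coverage_mask(matrix)
    weights = np.full(n, np.nan)
    if not valid.any():
        warnings.warn("all bins below coverage floor; all weights missing")
        return NormalizationVector(weights, method, convergence_stat=np.nan)

    marg = matrix.marginals()
    raw_total = float(matrix._mat[np.ix_(valid, valid)].sum())

    def _rescale_to_total(w: np.ndarray) -> np.ndarray:
        mat = matrix._mat[np.ix_(valid, valid)]
        wv = w[valid]
        weighted_total = float((sp.diags(wv) @ mat @ sp.diags(wv)).sum())
        if weighted_total > 0 and raw_total > 0:
            w = w * np.sqrt(raw_total / weighted_total)
        return w

    if method == "VC":
        weights[valid] = 1.0 / marg[valid]
        return NormalizationVector(_rescale_to_total(weights), method)
    if method == "VC_SQRT":
        weights[valid] = 1.0 / np.sqrt(marg[valid])
        return NormalizationVector(_rescale_to_total(weights), method)

    # balanced: Sinkhorn-style iterative proportional fitting
    sub = matrix._mat[np.ix_(valid, valid)].tocsr()
    w = np.ones(int(valid.sum()))
    stat = np.inf
    converged = False
    for _ in range(max_iter):
        rs = w * np.asarray(sub @ w).ravel()
        if np.any(rs <= 0):  # isolated bins that slipped the floor
            dead = rs <= 0
            w[dead] = np.nan
            keep = ~dead
            idx = np.where(valid)[0]
            valid[idx[dead]] = False
            sub = matrix._mat[np.ix_(valid, valid)].tocsr()
            w = w[keep]
            if w.size == 0:
                warnings.warn("balancing removed every bin")
                return NormalizationVector(weights, method, convergence_stat=np.nan)
            continue
        mean_rs = rs.mean()
        stat = float(rs.std() / mean_rs)
        if stat < tol:
            converged = True
            break
        w = w / np.sqrt(rs / mean_rs)
    else:
        warnings.warn(f"balancing did not converge (rel SD {stat:.3g})")
    weights[:] = np.nan
    weights[valid] = w
    weights = _rescale_to_total(weights)
    return NormalizationVector(weights, method, convergence_stat=stat, converged=converged)


def apply_normalization(
    matrix: ContactMatrix, vector: NormalizationVector
) -> ContactMatrix:
    """Return the weighted matrix; entries touching missing bins are dropped."""
    if vector.weights.shape[0] != matrix.n_bins:
        raise ValueError("normalization vector does not match the bin table")
    w = np.where(np.isfinite(vector.weights), vector.weights, 0.0)
    scaled = sp.diags(w) @ matrix._mat @ sp.diags(w)
    scaled = sp.csr_matrix(scaled)
    scaled.eliminate_zeros()
    mask = matrix.mask & np.isfinite(vector.weights)
    return ContactMatrix(matrix.bin_table, scaled, vector.method, mask=mask)


@dataclass
class ExpectedProfile:
    """Mean contact value per genomic separation (in bins)."""

    distance_bins: np.ndarray
    expected_value: np.ndarray

    def at(self, d: Union[int, np.ndarray]) -> np.ndarray:
        return np.asarray(self.expected_value)[np.asarray(d)]


def expected_by_distance(matrix: ContactMatrix) -> ExpectedProfile:
    """Mean contact over valid-bin pairs at each separation.

    Zero-count pairs between valid bins count toward the denominator.
    """
    n = matrix.n_bins
    valid = matrix.mask
    coo = sp.triu(matrix._mat).tocoo()
    keep = valid[coo.row] & valid[coo.col]
    d = coo.col[keep] - coo.row[keep]
    sums = np.bincount(d, weights=coo.data[keep], minlength=n)
    # pair counts per separation among valid bins via autocorrelation
    v = valid.astype(np.float64)
    counts = np.empty(n)
    for dist in range(n):
        counts[dist] = float(v[: n - dist] @ v[dist:])
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.where(counts > 0, sums / counts, 0.0)
    return ExpectedProfile(np.arange(n), exp)


def observed_over_expected(
    matrix: ContactMatrix, profile: ExpectedProfile
) -> ContactMatrix:
    """Divide each entry by the expected value at its separation.

    Separations whose expected value is zero are dropped.
    """
    coo = sp.triu(matrix._mat).tocoo()
    d = coo.col - coo.row
    exp = profile.at(d)
    keep = exp > 0
    vals = coo.data[keep] / exp[keep]
    upper = sp.coo_matrix((vals, (coo.row[keep], coo.col[keep])), shape=coo.shape)
    full = upper.tocsr() + sp.triu(upper, k=1).T
    return ContactMatrix(
        matrix.bin_table, full, normalization_tag=matrix.normalization_tag + "/expected",
        mask=matrix.mask,
    )


# -- track I/O ----------------------------------------------------------


def write_bedgraph(
    bins: BinTable, values: np.ndarray, path: Union[str, Path]
) -> None:
    """Write a per-bin track as bedGraph; NaN bins are skipped."""
    values = np.asarray(values, dtype=float)
    starts, ends = bins.starts, bins.ends
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            if np.isfinite(v):
                fh.write(f"{bins.chrom}\t{s}\t{e}\t{_format_value(v)}\n")


def read_bedgraph(path: Union[str, Path], bins: BinTable) -> np.ndarray:
    """Read a bedGraph into a per-bin array (NaN where absent)."""
    out = np.full(bins.n_bins, np.nan)
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    idx = df["start"].to_numpy() // bins.bin_size
    out[idx] = df["value"].to_numpy(dtype=float)
    return out
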