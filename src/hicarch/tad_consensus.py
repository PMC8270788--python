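"""Internal insulation-based domain caller and multi-caller consensus.

The consensus procedure merges candidate domain sets, aligns nearby
boundaries to the lowest-insulation bin, filters domains by diamond
score, size and contact density, and compares domain sets by reciprocal
overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .domain_metrics import DiamondScore, InsulationTrack, diamond_score
from .matrix_core import ContactMatrix

__all__ = [
    "Domain",
    "DomainSet",
    "call_domains_insulation",
    "merge_domain_sets",
    "filter_domains",
    "low_density_filter",
    "compare_domain_sets",
    "OverlapReport",
    "read_domain_bed",
    "write_domain_bed",
]

DEFAULT_MERGE_WINDOW_BINS = 4
DEFAULT_DS_MIN = 0.6
DEFAULT_MIN_SIZE_BP = 100_000
DEFAULT_DENSITY_QUANTILE = 0.05
DEFAULT_PROMINENCE = 0.1


@dataclass(frozen=True)
class Domain:
    """Genomic interval on the bin grid with per-domain annotations."""

    chrom: str
    start: int
    end: int
    source: Tuple[str, ...] = ()
    diamond: Optional[float] = None
    loop_domain: bool = False
    cluster: Optional[int] = None
    subcluster: Optional[str] = None
    di_bias: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty domain {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def bins(self, bin_size: int) -> Tuple[int, int]:
        return self.start // bin_size, self.end // bin_size


class DomainSet:
    """Ordered collection of domains on one chromosome's bin grid."""

    def __init__(
        self,
        domains: Sequence[Domain],
        bin_size: int,
        provenance: Optional[Dict] = None,
    ):
        ordered = sorted(domains, key=lambda d: (d.start, d.end))
        seen = set()
        for d in ordered:
            key = (d.chrom, d.start, d.end)
            if key in seen:
                raise ValueError(f"duplicate domain {key}")
            seen.add(key)
            if d.start % bin_size:
                raise ValueError("domain start off the bin grid")
        self.domains: List[Domain] = ordered
        self.bin_size = bin_size
        self.provenance: Dict = provenance or {}

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self):
        return iter(self.domains)

    def __getitem__(self, k: int) -> Domain:
        return self.domains[k]

    def replace_domains(self, domains: Sequence[Domain]) -> "DomainSet":
        return DomainSet(domains, self.bin_size, dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [d.chrom for d in self],
                "start": [d.start for d in self],
                "end": [d.end for d in self],
                "source": [",".join(d.source) or "." for d in self],
                "diamond": [d.diamond for d in self],
                "loop_domain": [d.loop_domain for d in self],
                "cluster": [d.cluster for d in self],
                "subcluster": [d.subcluster for d in self],
            }
        )


def call_domains_insulation(
    insulation: InsulationTrack,
    bin_size: int,
    chrom: str,
    min_depth: float = DEFAULT_PROMINENCE,
    min_size_bins: int = 2,
    source: str = "insulation",
) -> DomainSet:
    """Call domains between local insulation minima.

    Borders are local minima with prominence at least ``min_depth`` (in
    log2 units); domains are the intervals between consecutive borders
    that span at least ``min_size_bins`` bins.
    """
    vals = insulation.values
    filled = np.where(np.isfinite(vals), vals, np.nanmax(vals[np.isfinite(vals)]) if np.isfinite(vals).any() else 0.0)
    minima, _ = find_peaks(-filled, prominence=min_depth)
    minima = minima[np.isfinite(vals[minima])]
    if minima.size < 2:
        if minima.size == 0:
            warnings.warn("no insulation minima found; empty domain set")
        return DomainSet([], bin_size, {"callers": [source]})
    domains = []
    for a, b in zip(minima[:-1], minima[1:]):
        if b - a >= min_size_bins:
            domains.append(
                Domain(chrom, int(a) * bin_size, int(b) * bin_size, source=(source,))
            )
    return DomainSet(domains, bin_size, {"callers": [source]})


def _cluster_borders(
    borders: np.ndarray, insulation: np.ndarray, window_bins: int
) -> Dict[int, int]:
    """Greedy left-to-right chaining; representative = min-insulation bin.

    A border joins the current group when within ``window_bins`` of the
    group's last member; ties in insulation go to the leftmost bin.
    """
    mapping: Dict[int, int] = {}
    borders = np.unique(borders)
    groups: List[List[int]] = []
    for b in borders:
        if groups and b - groups[-1][-1] <= window_bins:
            groups[-1].append(int(b))
        else:
            groups.append([int(b)])
    for grp in groups:
        ins = [
            insulation[g] if 0 <= g < len(insulation) and np.isfinite(insulation[g]) else np.inf
            for g in grp
        ]
        rep = grp[int(np.argmin(ins))]  # argmin returns first (leftmost) on ties
        for g in grp:
            mapping[g] = rep
    return mapping


def merge_domain_sets(
    sets: Sequence[DomainSet],
    insulation: InsulationTrack,
    window_bins: int = DEFAULT_MERGE_WINDOW_BINS,
) -> DomainSet:
    """Union candidate sets and align boundaries within a bin window.

    Boundaries within ``window_bins`` of each other collapse to the
    member bin with the lowest insulation; exact duplicate domains are
    collapsed with their source labels concatenated.
    """
    if not sets:
        raise ValueError("no domain sets to merge")
    bin_size = sets[0].bin_size
    for s in sets:
        if s.bin_size != bin_size:
            raise ValueError("domain sets are on different bin grids")
    all_domains = [d for s in sets for d in s]
    if not all_domains:
        return DomainSet([], bin_size)
    borders = np.array(
        [d.start // bin_size for d in all_domains]
        + [d.end // bin_size for d in all_domains]
    )
    mapping = _cluster_borders(borders, insulation.values, window_bins)
    merged: Dict[Tuple[str, int, int], Tuple[str, ...]] = {}
    for d in all_domains:
        s_bin = mapping[d.start // bin_size]
        e_bin = mapping[d.end // bin_size]
        if e_bin <= s_bin:
            continue  # collapsed to a point
        key = (d.chrom, s_bin * bin_size, e_bin * bin_size)
        merged[key] = tuple(sorted(set(merged.get(key, ())) | set(d.source)))
    domains = [
        Domain(chrom, start, end, source=src)
        for (chrom, start, end), src in merged.items()
    ]
    prov = {"callers": sorted({c for s in sets for c in s.provenance.get("callers", [])})}
    return DomainSet(domains, bin_size, prov)


def filter_domains(
    domains: DomainSet,
    matrix: ContactMatrix,
    ds_min: float = DEFAULT_DS_MIN,
    min_size: int = DEFAULT_MIN_SIZE_BP,
) -> DomainSet:
    """Keep domains with diamond score >= ``ds_min`` and size >= ``min_size``.

    Removal reasons are recorded in the result's provenance under
    ``"removed"``; unscorable domains are removed and logged as such.
    """
    kept: List[Domain] = []
    removed: List[Dict] = []
    for d in domains:
        ds = diamond_score(matrix, d.start, d.end)
        if ds.value is None:
            removed.append({"domain": (d.start, d.end), "reason": "unscorable"})
            continue
        reasons = []
        if ds.value < ds_min:
            reasons.append(f"diamond<{ds_min}")
        if d.length < min_size:
            reasons.append(f"size<{min_size}")
        if reasons:
            removed.append({"domain": (d.start, d.end), "reason": ";".join(reasons)})
            continue
        kept.append(replace(d, diamond=ds.value))
    out = domains.replace_domains(kept)
    out.provenance["removed"] = removed
    return out


def low_density_filter(
    domains: DomainSet,
    raw_matrix: ContactMatrix,
    floor_quantile: float = DEFAULT_DENSITY_QUANTILE,
) -> DomainSet:
    """Drop domains whose mean intra-domain raw count is in the low tail.

    The floor is the ``floor_quantile`` quantile of all candidate
    domains' mean intra-domain counts; domains strictly below it are
    removed.
    """
    if len(domains) == 0 or floor_quantile <= 0:
        return domains.replace_domains(list(domains))
    dense = raw_matrix.to_dense()
    bs = domains.bin_size
    means = []
    for d in domains:
        s, e = d.bins(bs)
        means.append(float(dense[s:e, s:e].mean()))
    floor = float(np.quantile(means, floor_quantile))
    kept = [d for d, m in zip(domains, means) if m >= floor]
    out = domains.replace_domains(kept)
    out.provenance["density_floor"] = floor
    return out


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    matched: int
    unique_a: int
    unique_b: int
    mean_jaccard: float
    pairs: List[Tuple[int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_a": self.n_a,
                    "n_b": self.n_b,
                    "matched": self.matched,
                    "unique_a": self.unique_a,
                    "unique_b": self.unique_b,
                    "mean_jaccard": self.mean_jaccard,
                }
            ]
        )


def compare_domain_sets(
    a: DomainSet, b: DomainSet, min_fraction: float = 0.9
) -> OverlapReport:
    """Reciprocal-overlap matching between two domain sets.

    A pair matches when the overlap covers at least ``min_fraction`` of
    BOTH domains' lengths.
    """
    pairs: List[Tuple[int, int]] = []
    jaccards: List[float] = []
    matched_a, matched_b = set(), set()
    for ia, da in enumerate(a):
        for ib, db in enumerate(b):
            if da.chrom != db.chrom:
                continue
            ov = min(da.end, db.end) - max(da.start, db.start)
            if ov <= 0:
                continue
            if ov >= min_fraction * da.length and ov >= min_fraction * db.length:
                pairs.append((ia, ib))
                matched_a.add(ia)
                matched_b.add(ib)
                union = max(da.end, db.end) - min(da.start, db.start)
                jaccards.append(ov / union)
    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        matched=len(pairs),
        unique_a=len(a) - len(matched_a),
        unique_b=len(b) - len(matched_b),
        mean_jaccard=float(np.mean(jaccards)) if jaccards else np.nan,
        pairs=pairs,
    )


# -- BED I/O ------------------------------------------------------------


def write_domain_bed(domains: DomainSet, path: Union[str, Path]) -> None:
    """BED with score column 5 = diamond scaled 0-1000, full value in col 7."""
    with open(path, "w") as fh:
        for d in domains:
            score = 0 if d.diamond is None else int(round(min(max(d.diamond, 0), 1) * 1000))
            name = ",".join(d.source) or "."
            diamond = "." if d.diamond is None else repr(float(d.diamond))
            extras = [
                diamond,
                "loop" if d.loop_domain else "ordinary",
                "." if d.cluster is None else str(d.cluster),
                d.subcluster or ".",
            ]
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{score}\t.\t" + "\t".join(extras) + "\n"
            )


def read_domain_bed(path: Union[str, Path], bin_size: int) -> DomainSet:
    """Read candidate domains from BED (cols 1-3 required, col 4 = source)."""
    domains = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            source = (parts[3],) if len(parts) > 3 and parts[3] != "." else ()
            domains.append(Domain(chrom, start, end, source=source))
    return DomainSet(domains, bin_size)
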