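"""Loop filtering and loop-domain annotation.

Candidate loops (anchor pairs, e.g. from an external peak caller) are
filtered by contact distance and by local vanilla-coverage values, then
matched to domain corners to split domains into loop domains and
ordinary domains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .matrix_core import ContactMatrix
from .tad_consensus import Domain, DomainSet

__all__ = [
    "Loop",
    "filter_loops",
    "annotate_loop_domains",
    "read_bedpe",
    "write_bedpe",
]

DEFAULT_MAX_DISTANCE_BP = 2_000_000
DEFAULT_VC_FLOOR = 1.0
DEFAULT_NEIGHBORHOOD_BP = 5_000
DEFAULT_CORNER_TOL_BP = 50_000
DEFAULT_CORNER_TOL_FRACTION = 0.2


@dataclass(frozen=True)
class Loop:
    """Point interaction between two genomic anchors (bin-aligned bp)."""

    chrom: str
    anchor1_start: int
    anchor1_end: int
    anchor2_start: int
    anchor2_end: int
    resolution: int
    strength: Optional[float] = None

    def __post_init__(self) -> None:
        if self.anchor1_end > self.anchor2_start:
            raise ValueError("anchors must be non-overlapping, anchor1 upstream")

    @property
    def mid1(self) -> float:
        return (self.anchor1_start + self.anchor1_end) / 2.0

    @property
    def mid2(self) -> float:
        return (self.anchor2_start + self.anchor2_end) / 2.0

    @property
    def separation(self) -> float:
        return self.mid2 - self.mid1


def filter_loops(
    loops: Sequence[Loop],
    vc_matrix: ContactMatrix,
    max_distance: int = DEFAULT_MAX_DISTANCE_BP,
    vc_floor: float = DEFAULT_VC_FLOOR,
    neighborhood: int = DEFAULT_NEIGHBORHOOD_BP,
    stat: str = "min",
) -> List[Loop]:
    """Drop distal loops and loops whose neighborhood is weak in VC terms.

    A loop passes when its anchor-midpoint separation is at most
    ``max_distance`` and the ``stat`` (min or mean) of the VC-normalized
    matrix values in the square pixel window spanning
    ``+/-neighborhood`` bp around the loop pixel is at least
    ``vc_floor``. ``vc_matrix`` should be the vanilla-coverage
    normalized matrix at the loops' resolution.
    """
    if stat not in {"min", "mean"}:
        raise ValueError("stat must be 'min' or 'mean'")
    bs = vc_matrix.bin_table.bin_size
    if loops and loops[0].resolution != bs:
        raise ValueError(
            f"loop resolution {loops[0].resolution} != matrix bin size {bs}"
        )
    dense = vc_matrix.to_dense()
    n = vc_matrix.n_bins
    nb = max(0, neighborhood // bs)
    agg = np.min if stat == "min" else np.mean
    kept = []
    for lp in loops:
        if lp.separation > max_distance:
            continue
        b1, b2 = int(lp.mid1 // bs), int(lp.mid2 // bs)
        r0, r1 = max(0, b1 - nb), min(n, b1 + nb + 1)
        c0, c1 = max(0, b2 - nb), min(n, b2 + nb + 1)
        window = dense[r0:r1, c0:c1]
        if window.size and agg(window) >= vc_floor:
            kept.append(lp)
    return kept


def annotate_loop_domains(
    domains: DomainSet,
    loops: Sequence[Loop],
    tol_bp: int = DEFAULT_CORNER_TOL_BP,
    tol_fraction: float = DEFAULT_CORNER_TOL_FRACTION,
) -> DomainSet:
    """Flag domains whose corner carries a loop.

    A domain is a loop domain when some loop has anchor1 within ``tol``
    of its 5' border and anchor2 within ``tol`` of its 3' border, with
    ``tol = min(tol_bp, tol_fraction * domain_length)``.
    """
    out: List[Domain] = []
    for d in domains:
        tol = min(tol_bp, tol_fraction * d.length)
        flag = any(
            lp.chrom == d.chrom
            and abs(lp.mid1 - d.start) <= tol
            and abs(lp.mid2 - d.end) <= tol
            for lp in loops
        )
        out.append(replace(d, loop_domain=flag))
    return domains.replace_domains(out)


# -- BEDPE I/O ----------------------------------------------------------


def read_bedpe(path: Union[str, Path], resolution: int) -> List[Loop]:
    loops = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = line.split("\t")
            strength = float(p[7]) if len(p) > 7 and p[7] != "." else None
            loops.append(
                Loop(
                    chrom=p[0],
                    anchor1_start=int(p[1]),
                    anchor1_end=int(p[2]),
                    anchor2_start=int(p[4]),
                    anchor2_end=int(p[5]),
                    resolution=resolution,
                    strength=strength,
                )
            )
    return loops


def write_bedpe(loops: Sequence[Loop], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            strength = "." if lp.strength is None else repr(float(lp.strength))
            fh.write(
                f"{lp.chrom}\t{lp.anchor1_start}\t{lp.anchor1_end}\t"
                f"{lp.chrom}\t{lp.anchor2_start}\t{lp.anchor2_end}\t.\t{strength}\n"
            )
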