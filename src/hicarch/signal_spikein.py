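"""Spike-in scale factors and track scaling.

Library depth is estimated as the ratio of reads mapped to the target
genome over reads mapped to the spike-in genome; tracks are divided by
the factor so deeper target libraries are scaled down.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["SpikeInLibrary", "spike_scale_factor", "scale_track", "read_spike_counts"]


@dataclass(frozen=True)
class SpikeInLibrary:
    name: str
    n_target: int
    n_spike: int

    @property
    def scale_factor(self) -> float:
        return spike_scale_factor(self.n_target, self.n_spike)


def spike_scale_factor(n_target: int, n_spike: int) -> float:
    """Scale factor S = n_target / n_spike."""
    if n_target < 0 or n_spike < 0:
        raise ValueError("read counts must be non-negative")
    if n_spike == 0:
        raise ValueError("no spike-in reads; scale factor undefined")
    return n_target / n_spike


def scale_track(track: np.ndarray, s: float) -> np.ndarray:
    """Divide every value by the scale factor."""
    if s <= 0:
        raise ValueError("scale factor must be positive")
    return np.asarray(track, dtype=float) / s


def read_spike_counts(path: Union[str, Path]) -> dict:
    """Read libraries from TSV columns (library, genome, reads).

    Genome values 'target' and 'spike' select the two counts.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["library", "genome", "reads"])
    out = {}
    for name, grp in df.groupby("library"):
        counts = dict(zip(grp["genome"], grp["reads"]))
        out[name] = SpikeInLibrary(
            name=str(name),
            n_target=int(counts.get("target", 0)),
            n_spike=int(counts.get("spike", 0)),
        )
    return out
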