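"""Binned read-depth profiles.

A :class:`DepthProfile` holds, for one individual, the read count in each
fixed-width window tiling the 12 chromosomes.  Counts are integers for
simulated or observed data; the noise-free simulation mode produces exact
expected counts, which are fractional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, N_CHROMOSOMES

__all__ = ["DepthProfile"]


@dataclass
class DepthProfile:
    """Per-window read counts for one individual (0-based, half-open windows)."""

    individual_id: str
    chrom: np.ndarray  # int 1..12, one entry per window
    start: np.ndarray
    end: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.count) == n):
            raise ValueError("window arrays must have equal length")
        if np.any(np.asarray(self.count) < 0):
            raise ValueError("window counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return int(len(self.chrom))

    @property
    def total_count(self):
        return self.count.sum()

    def chromosome_counts(self) -> np.ndarray:
        """Summed window counts per chromosome, ordered by chromosome id."""
        out = np.zeros(N_CHROMOSOMES, dtype=float)
        np.add.at(out, np.asarray(self.chrom) - 1, self.count)
        return out

    def chromosomes_present(self) -> set[int]:
        return set(int(c) for c in np.unique(self.chrom))

    def window_mask(self, cid: int) -> np.ndarray:
        return np.asarray(self.chrom) == cid

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "count": self.count}
        )

    def validate_against(self, genome: GenomeSpec) -> None:
        """Check that windows exactly tile each chromosome of ``genome``."""
        wt = genome.windows()
        if self.n_windows != wt.n_windows:
            raise ValueError(
                f"{self.individual_id}: {self.n_windows} windows, "
                f"genome expects {wt.n_windows}"
            )
        if not (
            np.array_equal(np.asarray(self.chrom), wt.chrom)
            and np.array_equal(np.asarray(self.start), wt.start)
            and np.array_equal(np.asarray(self.end), wt.end)
        ):
            raise ValueError(
                f"{self.individual_id}: window coordinates do not tile the genome "
                f"at window size {genome.window_size}"
            )
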