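"""Genome model: chromosome specifications and fixed-width windowing.

The tetraploid rice genome is represented as 12 chromosomes, each with a
length, a centromere position (splitting it into a short and a long arm)
and a size relative to chromosome 1.  All coverage statistics downstream
are computed over fixed-width windows (10 kb by default) tiling each
chromosome; the final window of a chromosome may be short.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ChromosomeSpec",
    "GenomeSpec",
    "default_genome",
    "load_genome_table",
]

N_CHROMOSOMES = 12
DEFAULT_WINDOW_SIZE = 10_000


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical size, centromere and optional annotation counts.

    ``relative_size`` is the chromosome length divided by the length of
    chromosome 1 (chromosome 1 therefore has relative size exactly 1); it is
    the denominator of the per-chromosome coverage normalization.
    ``gene_count`` / ``link_count`` optionally carry the number of annotated
    genes and of predicted inter-chromosomal functional links, used only by
    the frequency-factor correlation.
    """

    id: int
    length: int
    centromere: int
    relative_size: float
    gene_count: int | None = None
    link_count: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.id <= N_CHROMOSOMES:
            raise ValueError(f"chromosome id must be 1..{N_CHROMOSOMES}, got {self.id}")
        if self.length <= 0:
            raise ValueError(f"chromosome {self.id}: length must be positive")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"chromosome {self.id}: centromere {self.centromere} outside (0, {self.length})"
            )
        if self.relative_size <= 0:
            raise ValueError(f"chromosome {self.id}: relative_size must be positive")

    @property
    def short_arm_length(self) -> int:
        return self.centromere

    @property
    def long_arm_length(self) -> int:
        return self.length - self.centromere


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of 12 chromosomes plus the window size used for binning."""

    chromosomes: tuple[ChromosomeSpec, ...]
    window_size: int = DEFAULT_WINDOW_SIZE

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chromosomes]
        if sorted(ids) != list(range(1, N_CHROMOSOMES + 1)):
            raise ValueError(
                f"genome must contain exactly chromosomes 1..{N_CHROMOSOMES}, got ids {ids}"
            )
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        chr1 = self.chromosome(1)
        if chr1.relative_size != 1.0:
            raise ValueError("relative_size of chromosome 1 must be exactly 1")
        for c in self.chromosomes:
            expected = c.length / chr1.length
            if abs(c.relative_size - expected) > 1e-9 * max(1.0, expected):
                raise ValueError(
                    f"chromosome {c.id}: relative_size {c.relative_size} != length ratio {expected}"
                )

    def chromosome(self, cid: int) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.id == cid:
                return c
        raise KeyError(f"no chromosome {cid}")

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def relative_sizes(self) -> np.ndarray:
        """Relative sizes ordered by chromosome id (index 0 = chromosome 1)."""
        return np.array([self.chromosome(i).relative_size for i in range(1, 13)])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.chromosome(i).length for i in range(1, 13)], dtype=np.int64)

    def windows(self) -> "WindowTable":
        """Fixed-width windows tiling every chromosome (cached per genome)."""
        table = _WINDOW_CACHE.get(id(self))
        if table is None:
            table = WindowTable.build(self)
            _WINDOW_CACHE[id(self)] = table
        return table


# Window tables are immutable per genome instance; cache keyed on object id.
_WINDOW_CACHE: dict[int, "WindowTable"] = {}


@dataclass(frozen=True)
class WindowTable:
    """Vectorized window coordinates for one genome.

    Arrays are parallel over windows, in chromosome-id then start order.
    ``arm`` is 0 for the short arm and 1 for the long arm, assigned by the
    window midpoint relative to the centromere.  ``short_arm_bp`` /
    ``long_arm_bp`` split each window's span at the centromere, so a window
    straddling the centromere contributes base pairs to both arms.
    """

    chrom: np.ndarray  # int, 1..12
    start: np.ndarray  # int, 0-based
    end: np.ndarray  # int, half-open
    arm: np.ndarray  # 0 = short (p), 1 = long (q)
    short_arm_bp: np.ndarray
    long_arm_bp: np.ndarray

    @classmethod
    def build(cls, genome: GenomeSpec) -> "WindowTable":
        chroms, starts, ends = [], [], []
        arms, sbp, lbp = [], [], []
        w = genome.window_size
        for cid in range(1, N_CHROMOSOMES + 1):
            spec = genome.chromosome(cid)
            st = np.arange(0, spec.length, w, dtype=np.int64)
            en = np.minimum(st + w, spec.length)
            mid = (st + en) / 2.0
            cen = spec.centromere
            chroms.append(np.full(st.size, cid, dtype=np.int64))
            starts.append(st)
            ends.append(en)
            arms.append((mid >= cen).astype(np.int64))
            sbp.append(np.clip(np.minimum(en, cen) - st, 0, None))
            lbp.append(np.clip(en - np.maximum(st, cen), 0, None))
        return cls(
            chrom=np.concatenate(chroms),
            start=np.concatenate(starts),
            end=np.concatenate(ends),
            arm=np.concatenate(arms),
            short_arm_bp=np.concatenate(sbp),
            long_arm_bp=np.concatenate(lbp),
        )

    @property
    def n_windows(self) -> int:
        return int(self.chrom.size)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start


def load_genome_table(path: str | Path, window_size: int = DEFAULT_WINDOW_SIZE) -> GenomeSpec:
    """Read a chromosome table CSV into a :class:`GenomeSpec`.

    Expected header: ``chrom,length,centromere[,gene_count,link_count]``.
    ``relative_size`` is derived from the lengths.
    """
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(row)
    if not rows:
        raise ValueError(f"empty genome table: {path}")
    lengths = {int(r["chrom"]): int(r["length"]) for r in rows}
    if 1 not in lengths:
        raise ValueError("genome table must include chromosome 1")
    chr1_len = lengths[1]
    specs = []
    for r in rows:
        cid = int(r["chrom"])
        gene = r.get("gene_count") or None
        link = r.get("link_count") or None
        specs.append(
            ChromosomeSpec(
                id=cid,
                length=int(r["length"]),
                centromere=int(r["centromere"]),
                relative_size=int(r["length"]) / chr1_len,
                gene_count=int(gene) if gene else None,
                link_count=int(link) if link else None,
            )
        )
    specs.sort(key=lambda c: c.id)
    return GenomeSpec(chromosomes=tuple(specs), window_size=window_size)


def default_genome(window_size: int = DEFAULT_WINDOW_SIZE) -> GenomeSpec:
    """The bundled rice genome: MSU7 chromosome lengths, approximate centromeres."""
    ref = resources.files("karyodepth.data") / "rice_chromosomes.csv"
    with resources.as_file(ref) as path:
        return load_genome_table(path, window_size=window_size)
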