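"""Normalized coverage ("Key value") and simulation-derived calling thresholds.

For one individual, the per-chromosome normalized coverage is

    key_i   = R_i × 12 / R_total / s_i
    value_i = key_i / mean(key_1 … key_12)

where R_i is the summed window read count of chromosome i, R_total the
genome-wide total, and s_i the chromosome's size relative to chromosome 1.
``key_i`` is proportional to the per-base-pair read rate of chromosome i;
dividing by the mean key makes the 12 values average exactly 1 for every
individual, so no euploid control individual is needed.

Gain/loss thresholds are obtained by simulating, for each chromosome, an
individual that gained (lost) exactly one copy and recording the altered
chromosome's normalized value.  With exact expected counts this has the
closed form

    expected_threshold(δ) = (1 + δ/4) × 12 / (12 + δ/4)

(= 60/49 ≈ 1.2245 for a single gain, 36/47 ≈ 0.7660 for a single loss),
independent of which chromosome is altered.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeSpec, N_CHROMOSOMES
from .karyotype import Karyotype
from .profiles import DepthProfile
from .simulate import SimConfig, simulate_profile

__all__ = [
    "NormalizedCoverage",
    "ThresholdSet",
    "normalized_coverage",
    "expected_threshold",
    "derive_thresholds",
    "GAIN_ONE",
    "LOSS_ONE",
]

BASELINE = 4

# Closed-form normalized values of a chromosome after gaining / losing one
# copy in an otherwise euploid tetraploid.
GAIN_ONE = 60 / 49
LOSS_ONE = 36 / 47


@dataclass(frozen=True)
class NormalizedCoverage:
    """Per-chromosome normalized coverage values for one individual."""

    individual_id: str
    values: np.ndarray  # 12 entries, mean exactly 1
    keys: np.ndarray
    mean_window_count: float

    def value(self, cid: int) -> float:
        return float(self.values[cid - 1])


def normalized_coverage(p: DepthProfile, genome: GenomeSpec) -> NormalizedCoverage:
    """Compute the normalized per-chromosome coverage of one profile."""
    present = p.chromosomes_present()
    missing = set(range(1, N_CHROMOSOMES + 1)) - present
    if missing:
        raise ValueError(
            f"{p.individual_id}: profile missing chromosomes {sorted(missing)}"
        )
    counts = p.chromosome_counts()
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"{p.individual_id}: zero total read count")
    keys = counts * N_CHROMOSOMES / total / genome.relative_sizes
    values = keys / keys.mean()
    return NormalizedCoverage(
        individual_id=p.individual_id,
        values=values,
        keys=keys,
        mean_window_count=float(total / p.n_windows),
    )


def expected_threshold(dosage_delta: int) -> float:
    """Closed-form normalized value of a chromosome at dosage 4 + δ.

    Assumes the other 11 chromosomes are euploid (the configuration used
    for threshold derivation).
    """
    if not -BASELINE <= dosage_delta <= BASELINE:
        raise ValueError(f"dosage delta {dosage_delta} outside ±{BASELINE}")
    return (1 + dosage_delta / BASELINE) * N_CHROMOSOMES / (N_CHROMOSOMES + dosage_delta / BASELINE)


@dataclass(frozen=True)
class ThresholdSet:
    """Per-chromosome gain/loss calling thresholds plus their averages."""

    gain: np.ndarray  # 12 entries
    loss: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.gain) != N_CHROMOSOMES or len(self.loss) != N_CHROMOSOMES:
            raise ValueError("thresholds must cover 12 chromosomes")
        if not np.all(self.loss < 1) or not np.all(self.gain > 1):
            raise ValueError("need loss threshold < 1 < gain threshold per chromosome")

    @property
    def average_gain(self) -> float:
        return float(np.mean(self.gain))

    @property
    def average_loss(self) -> float:
        return float(np.mean(self.loss))

    def for_chromosome(self, cid: int, use_average: bool = False) -> tuple[float, float]:
        if use_average:
            return self.average_gain, self.average_loss
        return float(self.gain[cid - 1]), float(self.loss[cid - 1])

    # -- serialization -----------------------------------------------------

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["chrom", "gain_threshold", "loss_threshold"])
            for i in range(N_CHROMOSOMES):
                writer.writerow([i + 1, repr(float(self.gain[i])), repr(float(self.loss[i]))])
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "ThresholdSet":
        path = Path(path)
        gain = np.empty(N_CHROMOSOMES)
        loss = np.empty(N_CHROMOSOMES)
        seen = set()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                cid = int(row["chrom"])
                gain[cid - 1] = float(row["gain_threshold"])
                loss[cid - 1] = float(row["loss_threshold"])
                seen.add(cid)
        if seen != set(range(1, N_CHROMOSOMES + 1)):
            raise ValueError(f"threshold table missing chromosomes: {path}")
        prov_path = path.with_suffix(path.suffix + ".json")
        provenance = {}
        if prov_path.exists():
            provenance = json.loads(prov_path.read_text())
        return cls(gain=gain, loss=loss, provenance=provenance)


def derive_thresholds(
    genome: GenomeSpec, cfg: SimConfig, n_reps: int = 3
) -> ThresholdSet:
    """Derive gain/loss thresholds from single-chromosome aneuploidy simulations.

    For every chromosome and direction, ``n_reps`` profiles with a ±1
    whole-chromosome karyotype are simulated at the configured depth; the
    altered chromosome's normalized value, averaged over replicates, is
    that chromosome's threshold.  Deterministic given ``cfg.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = np.random.SeedSequence([cfg.seed, 0x7468])
    seeds = iter(master.spawn(2 * N_CHROMOSOMES * n_reps))
    gain = np.empty(N_CHROMOSOMES)
    loss = np.empty(N_CHROMOSOMES)
    for direction, out in ((1, gain), (-1, loss)):
        for cid in range(1, N_CHROMOSOMES + 1):
            k = Karyotype.from_deltas(whole={cid: direction})
            vals = []
            for _ in range(n_reps):
                rng = np.random.default_rng(next(seeds))
                profile = simulate_profile(k, cfg, rng=rng, individual_id=f"thr{cid}")
                nc = normalized_coverage(profile, genome)
                vals.append(nc.value(cid))
            out[cid - 1] = float(np.mean(vals))
    return ThresholdSet(
        gain=gain,
        loss=loss,
        provenance={
            "n_reps": n_reps,
            "mean_depth": cfg.mean_depth,
            "noise": cfg.noise,
            "seed": cfg.seed,
            "n_reads": cfg.n_reads,
            "window_size": genome.window_size,
        },
    )
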