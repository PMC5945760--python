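"""Synthetic binned-coverage and trait data for arbitrary karyotypes.

The simulator works at the count level: sequencing a tetraploid individual
at mean haploid depth ``d`` with reads of length ``r`` is modeled as
distributing ``N = round(d × genome_length / r)`` reads over the genomic
windows with probabilities proportional to window length × local dosage.
A window in a region at dosage 4 + δ receives weight ``(4 + δ)/4`` per
base pair; windows spanning the centromere are split at the centromere so
each side is weighted by its own arm dosage.

Noise models:

* ``multinomial`` — reads are a single multinomial draw (total conserved
  exactly), matching fixed-yield sequencing;
* ``poisson`` — independent Poisson counts with the same means;
* ``none`` — exact expected counts (fractional), for algebraic checks.

An optional per-window log-normal mappability multiplier (fixed per
configuration, shared by all individuals) mimics locally elevated or
depressed coverage from copy-number differences between the two parental
subgenomes; it is off by default.

Trait matrices are generated with a *general* aneuploidy effect (a mean
shift applied to every aneuploid individual on a subset of traits) plus
*karyotype-specific* effects, on top of Gaussian noise — the two
phenotype categories the downstream statistics are meant to separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec, default_genome
from .karyotype import (
    EUPLOID,
    Karyotype,
    format_karyotype,
    parse_karyotype,
    study_records,
)
from .profiles import DepthProfile

__all__ = [
    "SimConfig",
    "TraitEffectModel",
    "SimulatedPopulation",
    "dosage_weights",
    "simulate_profile",
    "simulate_population",
    "simulate_traits",
    "study_frequencies",
    "DEFAULT_READ_LENGTH",
]

DEFAULT_READ_LENGTH = 125
BASELINE = 4

# Fraction of plants from the cross direction with the japonica cytoplasm,
# matching the 108:204 split of the resequenced population.
DEFAULT_P_NN99 = 108 / 312


@dataclass(frozen=True)
class SimConfig:
    """Coverage-simulation settings.

    mean_depth is the target mean coverage of the haploid reference
    (1.0 reproduces the depth at which the calling thresholds were
    derived); mappability_sd is the standard deviation of the per-window
    log-normal weight multiplier.
    """

    genome: GenomeSpec
    mean_depth: float = 1.0
    noise: str = "multinomial"  # multinomial | poisson | none
    mappability_sd: float = 0.0
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.mappability_sd < 0:
            raise ValueError("mappability_sd must be non-negative")
        if self.noise not in ("multinomial", "poisson", "none"):
            raise ValueError(f"unknown noise model: {self.noise!r}")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")

    @property
    def n_reads(self) -> int:
        return int(round(self.mean_depth * self.genome.total_length / self.read_length))


def dosage_weights(k: Karyotype, genome: GenomeSpec) -> np.ndarray:
    """Expected relative read weight of every window under karyotype ``k``.

    The weight of a window equals (dosage/4) × window length, with the
    span split at the centromere so that each side carries the dosage of
    its own arm.  Euploid windows therefore have weight equal to their
    length.
    """
    wt = genome.windows()
    idx = wt.chrom - 1
    whole = np.asarray(k.whole, dtype=float)
    dos_s = BASELINE + whole + np.asarray(k.short_arm, dtype=float)
    dos_l = BASELINE + whole + np.asarray(k.long_arm, dtype=float)
    if np.any(dos_s < 0) or np.any(dos_l < 0):
        raise ValueError("infeasible karyotype: dosage below zero")
    weights = (dos_s[idx] * wt.short_arm_bp + dos_l[idx] * wt.long_arm_bp) / BASELINE
    return weights


def _mappability_weights(cfg: SimConfig) -> np.ndarray:
    """Per-window log-normal multiplier, fixed for a given configuration."""
    n = cfg.genome.windows().n_windows
    if cfg.mappability_sd == 0:
        return np.ones(n)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6D61]))
    return np.exp(rng.normal(0.0, cfg.mappability_sd, size=n))


def simulate_profile(
    k: Karyotype,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    individual_id: str = "sim",
) -> DepthProfile:
    """Simulate one individual's binned coverage profile.

    Deterministic given ``cfg.seed`` (or an explicit generator, for use
    inside population loops).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    wt = cfg.genome.windows()
    weights = dosage_weights(k, cfg.genome) * _mappability_weights(cfg)
    p = weights / weights.sum()
    n_reads = cfg.n_reads
    if cfg.noise == "multinomial":
        counts = rng.multinomial(n_reads, p).astype(float)
    elif cfg.noise == "poisson":
        counts = rng.poisson(n_reads * p).astype(float)
    else:  # exact expected counts
        counts = n_reads * p
    return DepthProfile(
        individual_id=individual_id,
        chrom=wt.chrom.copy(),
        start=wt.start.copy(),
        end=wt.end.copy(),
        count=counts,
    )


# --------------------------------------------------------------------------
# Trait generation
# --------------------------------------------------------------------------


def _default_trait_names(n: int) -> tuple[str, ...]:
    return tuple(f"trait_{i + 1:02d}" for i in range(n))


@dataclass(frozen=True)
class TraitEffectModel:
    """How aneuploidy shifts the simulated trait means.

    ``general_effect`` maps trait index → mean shift applied to every
    aneuploid individual; the default depresses the first 12 of 21 traits
    by one noise standard deviation, reproducing a population where
    aneuploids are generally smaller and weaker than euploids.
    ``specific_effects`` are (karyotype, trait index, shift) triples
    applied only to individuals whose true karyotype matches exactly.
    """

    n_traits: int = 21
    trait_names: tuple[str, ...] | None = None
    baseline: float = 0.0
    general_effect: Mapping[int, float] | None = None
    specific_effects: Sequence[tuple[Karyotype | str, int, float]] = ()
    noise_sd: float = 1.0

    def resolved_names(self) -> tuple[str, ...]:
        names = self.trait_names or _default_trait_names(self.n_traits)
        if len(names) != self.n_traits:
            raise ValueError("trait_names length must equal n_traits")
        return tuple(names)

    def resolved_general(self) -> np.ndarray:
        shifts = np.zeros(self.n_traits)
        if self.general_effect is None:
            shifts[: min(12, self.n_traits)] = -self.noise_sd
        else:
            for idx, val in self.general_effect.items():
                if not 0 <= idx < self.n_traits:
                    raise ValueError(f"trait index {idx} out of range")
                shifts[idx] = val
        return shifts

    def resolved_specific(self) -> list[tuple[Karyotype, int, float]]:
        out = []
        for pattern, idx, shift in self.specific_effects:
            k = parse_karyotype(pattern) if isinstance(pattern, str) else pattern
            if not 0 <= idx < self.n_traits:
                raise ValueError(f"trait index {idx} out of range")
            out.append((k, idx, float(shift)))
        return out


@dataclass
class SimulatedPopulation:
    """Profiles, ground-truth karyotypes and (optionally) traits for n plants."""

    profiles: list[DepthProfile]
    truth: dict[str, Karyotype]
    traits: pd.DataFrame | None
    cross_direction: dict[str, str]

    @property
    def individual_ids(self) -> list[str]:
        return [p.individual_id for p in self.profiles]

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_ids,
                "karyotype_string": [
                    format_karyotype(self.truth[i]) for i in self.individual_ids
                ],
                "cross_direction": [self.cross_direction[i] for i in self.individual_ids],
            }
        )


def simulate_population(
    freqs: Mapping[Karyotype | str, float],
    n: int,
    cfg: SimConfig,
    effect_model: TraitEffectModel | None = None,
    p_nn99: float = DEFAULT_P_NN99,
) -> SimulatedPopulation:
    """Simulate ``n`` individuals with karyotypes drawn from ``freqs``.

    Karyotype keys may be grammar strings or :class:`Karyotype` objects;
    probabilities must sum to 1.  Each individual gets its own generator
    derived from ``cfg.seed``, so single profiles are reproducible
    independently of population size.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    karyotypes = [
        parse_karyotype(k) if isinstance(k, str) else k for k in freqs.keys()
    ]
    probs = np.array(list(freqs.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"karyotype probabilities sum to {probs.sum()}, not 1")

    master = np.random.SeedSequence(cfg.seed)
    draw_rng = np.random.default_rng(master.spawn(1)[0])
    assignments = draw_rng.choice(len(karyotypes), size=n, p=probs)
    directions = np.where(draw_rng.random(n) < p_nn99, "NN99", "99NN")

    child_seeds = master.spawn(n + 1)
    profiles: list[DepthProfile] = []
    truth: dict[str, Karyotype] = {}
    cross: dict[str, str] = {}
    for i in range(n):
        iid = f"S{i + 1:04d}"
        k = karyotypes[assignments[i]]
        rng = np.random.default_rng(child_seeds[i])
        profiles.append(simulate_profile(k, cfg, rng=rng, individual_id=iid))
        truth[iid] = k
        cross[iid] = str(directions[i])

    traits = None
    if effect_model is not None:
        traits = simulate_traits(
            effect_model, truth, np.random.default_rng(child_seeds[n])
        )
    return SimulatedPopulation(profiles, truth, traits, cross)


def simulate_traits(
    model: TraitEffectModel,
    truth: Mapping[str, Karyotype],
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Draw a trait matrix for individuals with known true karyotypes."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    names = model.resolved_names()
    general = model.resolved_general()
    specific = model.resolved_specific()
    ids = list(truth.keys())
    values = np.full((len(ids), model.n_traits), model.baseline, dtype=float)
    for row, iid in enumerate(ids):
        k = truth[iid]
        if not k.is_euploid:
            values[row] += general
        for pattern, idx, shift in specific:
            if k == pattern:
                values[row, idx] += shift
    values += rng.normal(0.0, model.noise_sd, size=values.shape)
    df = pd.DataFrame(values, columns=list(names))
    df.insert(0, "individual_id", ids)
    return df


def study_frequencies(n_euploid: int = 188) -> dict[Karyotype, float]:
    """Karyotype frequencies of the study population.

    Parseable aneuploid karyotypes are weighted by their plant counts; the
    one record with unsupported fractional-arm notation contributes its
    plants to the euploid pool (it cannot be simulated), alongside the
    ``n_euploid`` euploid plants.
    """
    records = study_records()
    weights: dict[Karyotype, float] = {EUPLOID: float(n_euploid)}
    for rec in records:
        if rec.karyotype is None:
            weights[EUPLOID] += rec.n_plants
            continue
        weights[rec.karyotype] = weights.get(rec.karyotype, 0.0) + rec.n_plants
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


def demo_config(seed: int = 0, window_size: int = 10_000, **kwargs) -> SimConfig:
    """A 1×-depth configuration on the bundled rice genome."""
    return SimConfig(genome=default_genome(window_size), seed=seed, **kwargs)
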