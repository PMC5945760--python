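"""Population-level statistics of aneuploidy occurrence and retention.

Covers four questions about a karyotyped population:

* Is chromosome gain more frequent than loss?  (exact binomial test with
  success probability 0.5 on gain/loss counts)
* Do individual chromosomes deviate from a common event rate?  (exact
  two-sided Poisson test per chromosome)
* Which chromosomes are *prone* or *resistant* to aneuploidization?
  (per-chromosome event counts compared against 95%/5% thresholds from a
  Poisson permutation null sharing the observed mean rate)
* Do aneuploidy frequencies correlate with chromosome-level factors such
  as gene counts or inter-chromosomal functional links?  (Pearson
  correlation)

A reciprocal-cross bias test (Pearson chi-squared on a 2×2 table of
aneuploid/euploid counts by cross direction) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import N_CHROMOSOMES
from .karyotype import KaryotypeRecord, tabulate_records

__all__ = [
    "GainLossCounts",
    "PropensityResult",
    "CorrelationResult",
    "binomial_gain_loss",
    "exact_poisson_test",
    "propensity_classification",
    "reciprocal_bias_test",
    "frequency_factor_correlation",
    "gain_loss_counts",
]


@dataclass(frozen=True)
class GainLossCounts:
    """Counts of gain vs loss events in one aneuploidy context."""

    context: str  # 'simple' or 'compound'
    gains: int
    losses: int

    def __post_init__(self) -> None:
        if self.gains < 0 or self.losses < 0:
            raise ValueError("counts must be non-negative")


def binomial_gain_loss(c: GainLossCounts) -> float:
    """Exact two-sided binomial p-value for gain/loss symmetry (p0 = 0.5).

    Two-sided in the minimum-likelihood sense: the sum of probabilities of
    all outcomes no more likely than the observed count.
    """
    n = c.gains + c.losses
    if n == 0:
        raise ValueError("no gain/loss events to test")
    return float(stats.binomtest(c.gains, n, 0.5).pvalue)


def exact_poisson_test(observed: int, expected: float) -> float:
    """Exact two-sided Poisson test of ``observed`` against rate ``expected``.

    The p-value sums the Poisson(expected) masses of all outcomes whose
    probability does not exceed that of the observed count (the same
    convention as the two-sided binomial test above).
    """
    if expected <= 0:
        raise ValueError("expected rate must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    # Enumerate far enough into the upper tail that the truncated mass is
    # below double precision: mean + 40 sd covers it for any usable rate.
    upper = int(max(observed, expected + 40 * np.sqrt(expected) + 50))
    k = np.arange(0, upper + 1)
    pmf = stats.poisson.pmf(k, expected)
    p_obs = pmf[observed] if observed <= upper else 0.0
    # 1 + 1e-7 guard against ties lost to floating-point rounding,
    # matching the convention of R's poisson.test / binom.test.
    p = pmf[pmf <= p_obs * (1 + 1e-7)].sum()
    if p > 1 - 1e-12:  # every outcome included: p is 1 up to float noise
        return 1.0
    return float(p)


@dataclass(frozen=True)
class PropensityResult:
    """Prone/resistant/neutral classification of the 12 chromosomes."""

    category: str  # 'gain', 'loss' or 'gain_and_loss'
    observed: np.ndarray  # 12 counts
    classification: tuple[str, ...]  # per chromosome
    upper_threshold: float  # count at 95% probability
    lower_threshold: float  # count at 5% probability
    lam: float
    n_perm: int
    seed: int

    def chromosomes(self, label: str) -> list[int]:
        return [i + 1 for i, c in enumerate(self.classification) if c == label]


def _nearest_rank(sorted_draws: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q·n)-th smallest pooled draw."""
    n = sorted_draws.size
    rank = int(np.ceil(q * n))
    rank = min(max(rank, 1), n)
    return float(sorted_draws[rank - 1])


def propensity_classification(
    counts: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
    category: str = "gain_and_loss",
    zero_truncated: bool = False,
    pooled: bool = True,
) -> PropensityResult:
    """Classify chromosomes as prone/resistant to aneuploidization.

    The null model draws, in each of ``n_perm`` permutations, 12
    independent Poisson counts with rate equal to the mean of the observed
    counts.  By default all pooled draws form one empirical distribution
    whose 95th/5th nearest-rank percentiles are the upper/lower
    thresholds; ``pooled=False`` instead takes the thresholds from the
    distributions of per-permutation maxima and minima.  A chromosome is
    *prone* when its observed count exceeds the upper threshold and
    *resistant* when it falls below the lower one.

    ``zero_truncated=True`` restricts the null to positive integers
    (resampling zeros), for the reading of the null as "Poisson
    distributed positive integers".
    """
    observed = np.asarray(counts, dtype=int)
    if observed.shape != (N_CHROMOSOMES,):
        raise ValueError(f"need counts for {N_CHROMOSOMES} chromosomes")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    lam = float(observed.mean())
    if lam <= 0:
        raise ValueError("degenerate null: all observed counts are zero")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x70726F]))
    draws = rng.poisson(lam, size=(n_perm, N_CHROMOSOMES))
    if zero_truncated:
        zeros = draws == 0
        while zeros.any():
            draws[zeros] = rng.poisson(lam, size=int(zeros.sum()))
            zeros = draws == 0

    if pooled:
        pooled_sorted = np.sort(draws.ravel())
        upper = _nearest_rank(pooled_sorted, 0.95)
        lower = _nearest_rank(pooled_sorted, 0.05)
    else:
        upper = _nearest_rank(np.sort(draws.max(axis=1)), 0.95)
        lower = _nearest_rank(np.sort(draws.min(axis=1)), 0.05)

    classification = tuple(
        "prone" if o > upper else "resistant" if o < lower else "neutral"
        for o in observed
    )
    return PropensityResult(
        category=category,
        observed=observed,
        classification=classification,
        upper_threshold=upper,
        lower_threshold=lower,
        lam=lam,
        n_perm=n_perm,
        seed=seed,
    )


def reciprocal_bias_test(
    table: np.ndarray | Sequence[Sequence[int]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test (1 df) on a 2×2 aneuploid/euploid ×
    cross-direction table.  Returns (statistic, p); Yates continuity
    correction is off by default."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2×2 table")
    if np.any(table < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res[0]), float(res[1])


@dataclass(frozen=True)
class CorrelationResult:
    factor: str
    r: float
    p: float
    n: int


def frequency_factor_correlation(
    frequencies: Sequence[float],
    factor_values: Sequence[float],
    factor_name: str = "factor",
) -> CorrelationResult:
    """Pearson correlation between per-chromosome aneuploidy frequencies
    and a chromosome-level factor (gene count, link count, size …)."""
    x = np.asarray(frequencies, dtype=float)
    y = np.asarray(factor_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequencies and factor values must be paired")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        factor=factor_name, r=float(res.statistic), p=float(res.pvalue), n=x.size
    )


def gain_loss_counts(records: Iterable[KaryotypeRecord]) -> dict[str, GainLossCounts]:
    """Gain/loss counts from a karyotype table, under both conventions.

    ``simple``: plants carrying a single ±1 whole-chromosome karyotype.
    ``compound_individuals``: plants with a non-simple karyotype counted
    once per direction they involve (a plant with both a gain and a loss
    appears in both counts).  ``compound_events``: chromosome-level
    events, each involved chromosome counted once per plant.  Unparseable
    records are excluded (their dosage content is unknown).
    """
    from .karyotype import classify_karyotype

    records = list(records)
    simple_g = simple_l = 0
    ind_g = ind_l = 0
    ev_g = ev_l = 0
    for rec in records:
        if rec.karyotype is None or rec.karyotype.is_euploid:
            continue
        cls = classify_karyotype(rec.karyotype)
        if cls.category == "simple_gain":
            simple_g += rec.n_plants
            continue
        if cls.category == "simple_loss":
            simple_l += rec.n_plants
            continue
        gained = rec.karyotype.gained_chromosomes()
        lost = rec.karyotype.lost_chromosomes()
        if gained:
            ind_g += rec.n_plants
        if lost:
            ind_l += rec.n_plants
        ev_g += rec.n_plants * len(gained)
        ev_l += rec.n_plants * len(lost)
    return {
        "simple": GainLossCounts("simple", simple_g, simple_l),
        "compound_individuals": GainLossCounts("compound", ind_g, ind_l),
        "compound_events": GainLossCounts("compound", ev_g, ev_l),
    }
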