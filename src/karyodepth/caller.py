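"""Per-individual aneuploidy calling from binned coverage.

Calling proceeds in two stages mirroring the two criteria of the
karyotyping pipeline:

1. *Whole-chromosome calls* — each chromosome's normalized coverage is
   compared against the simulation-derived gain/loss thresholds; values
   crossing a threshold are assigned the nearest expected dosage level
   (|δ| ≤ 2).
2. *Arm-level calls* — the same statistic computed per arm (windows are
   assigned to arms by their midpoints).  When the two arms of a
   chromosome sit at different dosage levels, the whole-chromosome call
   is replaced by the arm calls — this is what turns, e.g., a long-arm
   gain into ``+1L`` rather than a diluted whole-chromosome signal.

Because the normalized values of one individual average exactly 1 by
construction, an individual carrying several gained chromosomes has its
baseline dragged upward and every value compressed toward 1 (three gains
compress a true +1 signal from 1.25 to ≈ 1.18, below the gain
threshold).  The caller therefore rescales values by the *median* of the
12 chromosome values before threshold comparison: the median is the
euploid baseline whenever fewer than six chromosomes are altered, which
holds for every karyotype within calling range.

Each called event carries a window-consistency fraction: the share of
the affected windows whose count ratio lies on the called side of the
midpoint between adjacent dosage levels.  Events with consistency below
0.8 are downgraded to no-call.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeSpec, N_CHROMOSOMES
from .karyotype import (
    Karyotype,
    KaryotypeClass,
    classify_karyotype,
    format_karyotype,
)
from .profiles import DepthProfile
from .thresholds import (
    NormalizedCoverage,
    ThresholdSet,
    expected_threshold,
    normalized_coverage,
)

__all__ = [
    "KaryotypeCall",
    "call_whole_chromosomes",
    "call_arms",
    "call_individual",
    "call_from_chromosome_counts",
    "write_calls_csv",
    "MAX_ABS_DELTA",
    "MIN_ARM_WINDOWS",
    "CONSISTENCY_CUTOFF",
]

logger = logging.getLogger(__name__)

MAX_ABS_DELTA = 2  # largest |copy-number change| the caller assigns
MIN_ARM_WINDOWS = 3
CONSISTENCY_CUTOFF = 0.8
BASELINE = 4


@dataclass
class KaryotypeCall:
    """The caller's verdict for one individual."""

    individual_id: str
    karyotype: Karyotype
    classification: KaryotypeClass
    values: np.ndarray  # per-chromosome normalized values (mean 1)
    arm_values: np.ndarray  # (12, 2): short, long; NaN where arm too short
    consistency: dict[tuple[int, str], float]  # (chrom, 'whole'|'S'|'L') → fraction
    warnings: list[str] = field(default_factory=list)

    @property
    def karyotype_string(self) -> str:
        return format_karyotype(self.karyotype)


def _dosage_estimates(values: np.ndarray) -> np.ndarray:
    """Rescale mean-normalized values to absolute dosage ratios (euploid = 1)."""
    med = float(np.median(values))
    if med <= 0:
        raise ValueError("degenerate profile: median normalized value is zero")
    return values / med


def _call_one(value: float, gain_t: float, loss_t: float) -> int:
    """Threshold comparison + nearest-expected-level magnitude assignment.

    Comparison is inclusive: a value exactly on a threshold is called.
    """
    if loss_t < value < gain_t:
        return 0
    if value >= gain_t:
        candidates = range(1, MAX_ABS_DELTA + 1)
    else:
        candidates = range(-MAX_ABS_DELTA, 0)
    return min(candidates, key=lambda d: abs(value - expected_threshold(d)))


def call_whole_chromosomes(
    nc: NormalizedCoverage, thresholds: ThresholdSet, use_average: bool = False
) -> np.ndarray:
    """Integer copy-number deltas for the 12 chromosomes of one individual."""
    est = _dosage_estimates(nc.values)
    deltas = np.zeros(N_CHROMOSOMES, dtype=int)
    for cid in range(1, N_CHROMOSOMES + 1):
        gain_t, loss_t = thresholds.for_chromosome(cid, use_average)
        deltas[cid - 1] = _call_one(float(est[cid - 1]), gain_t, loss_t)
    return deltas


def _arm_values(
    p: DepthProfile, genome: GenomeSpec, keys_mean: float, total: float
) -> tuple[np.ndarray, np.ndarray]:
    """Arm-level normalized values on the same scale as chromosome values.

    Returns (values, n_windows), both shaped (12, 2); NaN where an arm has
    fewer than MIN_ARM_WINDOWS windows.
    """
    wt = genome.windows()
    chr1_len = genome.chromosome(1).length
    values = np.full((N_CHROMOSOMES, 2), np.nan)
    n_win = np.zeros((N_CHROMOSOMES, 2), dtype=int)
    counts = np.asarray(p.count, dtype=float)
    win_len = wt.lengths
    for cid in range(1, N_CHROMOSOMES + 1):
        in_chrom = wt.chrom == cid
        for arm_idx in (0, 1):
            mask = in_chrom & (wt.arm == arm_idx)
            n = int(mask.sum())
            n_win[cid - 1, arm_idx] = n
            if n < MIN_ARM_WINDOWS:
                continue
            arm_count = counts[mask].sum()
            arm_len = win_len[mask].sum()
            key = arm_count * N_CHROMOSOMES / total / (arm_len / chr1_len)
            values[cid - 1, arm_idx] = key / keys_mean
    return values, n_win


def _consistency(
    ratios: np.ndarray, delta: int
) -> float:
    """Fraction of windows whose count ratio sits on the called side of
    the boundary between adjacent dosage levels.

    The boundary is the midpoint between the euploid level (1) and the
    first level in the called direction (1 ± 1/4), i.e. 1 ± 1/8: the
    check confirms that the windows genuinely sit on the aneuploid side,
    independently of the magnitude assigned to the event.
    """
    sign = 1 if delta > 0 else -1
    midpoint = 1 + sign / (2 * BASELINE)
    if sign > 0:
        return float(np.mean(ratios >= midpoint))
    return float(np.mean(ratios <= midpoint))


def call_arms(
    p: DepthProfile,
    genome: GenomeSpec,
    thresholds: ThresholdSet,
    whole_calls: np.ndarray,
    use_average: bool = False,
    downgrade: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, str], float], list[str]]:
    """Arm-level dosage calls and window-consistency fractions.

    Returns (arm_deltas (12, 2), arm_values (12, 2), consistency, warnings).
    Arm deltas for arms too short to call are set to the whole-chromosome
    call (no independent arm evidence), with a warning.  With
    ``downgrade=True`` (the stand-alone behaviour) arm calls failing the
    consistency cutoff are zeroed here; :func:`call_individual` instead
    defers downgrading to the merge step, so that an arm call which
    merely corroborates a whole-chromosome call is never vetoed by its
    own (noisier) arm-level consistency.
    """
    nc = normalized_coverage(p, genome)
    baseline = float(np.median(nc.values))
    total = float(np.asarray(p.count).sum())
    arm_vals, n_win = _arm_values(p, genome, float(nc.keys.mean()), total)

    wt = genome.windows()
    counts = np.asarray(p.count, dtype=float)
    # Per-window count ratio relative to the euploid expectation; the
    # baseline per-bp rate comes from the median chromosome rate.
    rates = p.chromosome_counts() / genome.lengths
    base_rate = float(np.median(rates))
    ratios = counts / (base_rate * wt.lengths)

    deltas = np.zeros((N_CHROMOSOMES, 2), dtype=int)
    consistency: dict[tuple[int, str], float] = {}
    warnings: list[str] = []
    for cid in range(1, N_CHROMOSOMES + 1):
        gain_t, loss_t = thresholds.for_chromosome(cid, use_average)
        for arm_idx, arm_name in ((0, "S"), (1, "L")):
            if n_win[cid - 1, arm_idx] < MIN_ARM_WINDOWS:
                deltas[cid - 1, arm_idx] = whole_calls[cid - 1]
                warnings.append(
                    f"chr{cid:02d}{arm_name}: arm too short for calling "
                    f"({n_win[cid - 1, arm_idx]} windows)"
                )
                continue
            est = arm_vals[cid - 1, arm_idx] / baseline
            d = _call_one(float(est), gain_t, loss_t)
            if d != 0:
                mask = (wt.chrom == cid) & (wt.arm == arm_idx)
                frac = _consistency(ratios[mask], d)
                consistency[(cid, arm_name)] = frac
                if downgrade and frac < CONSISTENCY_CUTOFF:
                    warnings.append(
                        f"chr{cid:02d}{arm_name}: call {d:+d} downgraded to no-call "
                        f"(window consistency {frac:.2f} < {CONSISTENCY_CUTOFF})"
                    )
                    d = 0
            deltas[cid - 1, arm_idx] = d
    return deltas, arm_vals, consistency, warnings


def call_individual(
    p: DepthProfile,
    genome: GenomeSpec,
    thresholds: ThresholdSet,
    use_average: bool = False,
) -> KaryotypeCall:
    """Assemble whole-chromosome and arm calls into a classified karyotype."""
    nc = normalized_coverage(p, genome)
    whole_calls = call_whole_chromosomes(nc, thresholds, use_average)
    arm_deltas, arm_vals, consistency, warnings = call_arms(
        p, genome, thresholds, whole_calls, use_average, downgrade=False
    )

    wt = genome.windows()
    counts = np.asarray(p.count, dtype=float)
    rates = p.chromosome_counts() / genome.lengths
    base_rate = float(np.median(rates))
    ratios = counts / (base_rate * wt.lengths)

    whole = [0] * N_CHROMOSOMES
    short = [0] * N_CHROMOSOMES
    long_ = [0] * N_CHROMOSOMES
    for cid in range(1, N_CHROMOSOMES + 1):
        i = cid - 1
        d_s, d_l = int(arm_deltas[i, 0]), int(arm_deltas[i, 1])
        if d_s != d_l:
            # Second criterion: arms at different dosage levels override
            # the whole-chromosome call.  Consistency is enforced per arm
            # here, on the calls actually used.
            for arm_name, d_arm, slot in (("S", d_s, short), ("L", d_l, long_)):
                if d_arm == 0:
                    continue
                frac = consistency.get((cid, arm_name), 1.0)
                if frac < CONSISTENCY_CUTOFF:
                    warnings.append(
                        f"chr{cid:02d}{arm_name}: call {d_arm:+d} downgraded to "
                        f"no-call (window consistency {frac:.2f} < {CONSISTENCY_CUTOFF})"
                    )
                    continue
                slot[i] = d_arm
            continue
        d = int(whole_calls[i])
        if d != 0:
            frac = _consistency(ratios[wt.chrom == cid], d)
            consistency[(cid, "whole")] = frac
            if frac < CONSISTENCY_CUTOFF:
                warnings.append(
                    f"chr{cid:02d}: whole-chromosome call {d:+d} downgraded to "
                    f"no-call (window consistency {frac:.2f} < {CONSISTENCY_CUTOFF})"
                )
                d = 0
        whole[i] = d

    karyotype = Karyotype(tuple(whole), tuple(short), tuple(long_))
    for w in warnings:
        logger.warning("%s: %s", p.individual_id, w)
    return KaryotypeCall(
        individual_id=p.individual_id,
        karyotype=karyotype,
        classification=classify_karyotype(karyotype),
        values=nc.values,
        arm_values=arm_vals,
        consistency=consistency,
        warnings=warnings,
    )


def call_from_chromosome_counts(
    individual_id: str,
    counts: np.ndarray,
    genome: GenomeSpec,
    thresholds: ThresholdSet,
    use_average: bool = False,
) -> KaryotypeCall:
    """Whole-chromosome-only calling from per-chromosome read totals.

    This is the mode used for idxstats-style input, where no window-level
    distribution (and hence no arm call or consistency check) is available.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_CHROMOSOMES,):
        raise ValueError("need one count per chromosome")
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"{individual_id}: zero total read count")
    keys = counts * N_CHROMOSOMES / total / genome.relative_sizes
    values = keys / keys.mean()
    nc = NormalizedCoverage(individual_id, values, keys, float(total / N_CHROMOSOMES))
    deltas = call_whole_chromosomes(nc, thresholds, use_average)
    karyotype = Karyotype.from_deltas(
        whole={cid: int(deltas[cid - 1]) for cid in range(1, N_CHROMOSOMES + 1)}
    )
    return KaryotypeCall(
        individual_id=individual_id,
        karyotype=karyotype,
        classification=classify_karyotype(karyotype),
        values=values,
        arm_values=np.full((N_CHROMOSOMES, 2), np.nan),
        consistency={},
    )


def write_calls_csv(calls: list[KaryotypeCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "individual_id",
                "karyotype_string",
                "category",
                "is_segmental",
                "is_hidden",
                "chromosome_number",
            ]
        )
        for call in calls:
            cls = call.classification
            writer.writerow(
                [
                    call.individual_id,
                    call.karyotype_string,
                    cls.category,
                    cls.is_segmental,
                    cls.is_hidden,
                    "" if cls.chromosome_number is None else cls.chromosome_number,
                ]
            )


def write_values_csv(calls: list[KaryotypeCall], path: str | Path) -> None:
    """Per-chromosome normalized values for every called individual."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id"] + [f"chr{c:02d}" for c in range(1, 13)])
        for call in calls:
            writer.writerow([call.individual_id] + [f"{v:.6f}" for v in call.values])
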