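# Methods

## The dosage model

The population is a synthetic segmental allotetraploid rice: 12 chromosomes
at baseline copy number 4 (48 chromosomes). A karyotype stores, per
chromosome, integer deviations from that baseline — one for the whole
chromosome and one for each arm (short arm S, long arm L), so `"+2S Chr10"`
means the short arm of chromosome 10 is present in six copies. Because the
two parental subgenomes recombine freely and reads from either subgenome
map to a single reference, all dosages are *combined* across subgenomes;
the pipeline never attributes a gained or lost copy to one parent. For the
same reason only 24 thresholds are derived (12 chromosomes × gain/loss)
rather than one pair per subgenome copy: at the count level the two
parental copies of a chromosome are indistinguishable, and the downstream
rules only ever use the per-chromosome (or averaged) thresholds.

Classification taxonomy: *euploid* (no deviation), *simple gain/loss*
(exactly one whole chromosome at ±1, nothing else), *compound* (everything
else, including multi-copy changes of a single chromosome and all arm-level
changes), with two orthogonal flags — *segmental* (any arm-level term) and
*hidden* (whole-chromosome gains and losses cancelling to a balanced 48).
Chromosome number (48 + net whole-chromosome change) is reported only for
karyotypes free of arm terms; there is no defensible convention for how an
extra or missing arm counts toward a chromosome total, so such karyotypes
report "undefined" and are excluded from range summaries.

The bundled karyotype table transcribes the study population's 55 aneuploid
karyotypes and plant counts. One record carries a fractional-arm term
("+ 1/2S") outside the grammar; it is kept raw, counted in plant totals and
flagged segmental from its textual arm terms, but excluded from every
dosage-dependent computation.

## Coverage simulation

Sequencing is modeled at the count level: `N = round(depth ×
genome_length / read_length)` reads (125-bp reads at 1× haploid depth by
default, matching the regime in which the thresholds are calibrated) are
distributed over 10-kb windows with probabilities proportional to window
length × local dosage/4. Windows spanning a centromere are split at the
centromere so each side carries its own arm dosage. Three noise modes:
`multinomial` (one draw per individual; total count conserved exactly),
`poisson` (independent windows, same means), and `none` (exact expected
counts, used for algebraic checks). An optional log-normal per-window
multiplier, fixed per configuration and shared by all individuals, mimics
the scattered high/low windows that copy-number differences between the
parental subgenomes produce in real data; it defaults to off.

What the simulator deliberately does not model: GC or fragment-length bias,
mappability structure tied to real sequence, genuine subgenome CNVs,
mosaicism (every plant has one constitutive karyotype), or read-level
artifacts. Passing recovery tests therefore demonstrates that the calling
rules are correct and well-calibrated for multinomial/Poisson counting
noise at the stated depth — not that the pipeline is robust to every bias
of real libraries.

Trait matrices are drawn as baseline + a *general* shift applied to every
aneuploid (default −1 noise SD on 12 of 21 traits, reproducing a population
where aneuploids are generally smaller and weaker) + *karyotype-specific*
shifts for exact-match carriers + Gaussian noise (SD 1). Population
defaults mirror the study design: 312 plants, ~40% aneuploid with
karyotype frequencies from the bundled table, reciprocal-cross directions
at 108:204.

## Normalization and thresholds

Per-chromosome normalized coverage: `key_i = R_i·12/R_total/s_i` with `s_i`
the size of chromosome *i* relative to chromosome 1, then `value_i =
key_i / mean(key)`. The mean of the 12 values is exactly 1 for every
individual by construction — this is what removes the need for a euploid
control. `key_i` is proportional to the chromosome's per-base-pair read
rate, so the same formula applied to arm read counts and arm lengths gives
arm-level values on the same scale.

Thresholds come from simulating single-chromosome gains and losses at the
calibration depth (default 1×, 3 replicates per chromosome and direction,
averaged). With noise off the derivation is exact and size-independent:
`expected_threshold(δ) = (1 + δ/4)·12/(12 + δ/4)`, giving 60/49 for +1 and
36/47 for −1. At 1× depth a chromosome's Monte-Carlo threshold is within
±0.01 of the closed form (binomial sampling error of a ~200k-read
chromosome count is ~0.2–0.3%).

## Calling rules

Mean normalization has a side effect the caller must undo: an individual
with several gained chromosomes has its own mean dragged up, compressing
every value toward 1 (with three +1 chromosomes, the true signal 1.25
appears as ≈1.18, below the 60/49 threshold). The caller therefore
rescales values by the *median* of the 12 chromosome values before
threshold comparison. The median equals the euploid baseline whenever
fewer than six chromosomes are altered — true for every karyotype in
calling range — making the rescaled values estimates of absolute dosage/4.

Comparison with the per-chromosome thresholds is inclusive (a value exactly
on a threshold is called). Values crossing a threshold are assigned the
integer dosage change whose expected level is nearest, restricted to
|δ| ≤ 2 with the sign fixed by the crossed side; larger changes do not
occur in the observed karyotype spectrum and are out of calling range.

Arm-level calling applies the same statistic to arm window sums (windows
assigned to arms by midpoint; arms with fewer than 3 windows are not
independently callable and inherit the whole-chromosome call with a
warning). When the two arms of a chromosome land on different dosage
levels, the arm calls replace the whole-chromosome call — that is what
turns a long-arm gain into `+1L` instead of a diluted whole-chromosome
signal.

Every call actually used is backed by a window-consistency check: the
fraction of the affected windows whose count ratio (window count /
euploid expectation from the median per-bp rate) lies on the called side
of the boundary between the euploid level and the first level in the
called direction (1 ± 1/8). Calls below 0.8 consistency are downgraded to
no-call with a warning. Two numerical choices matter here:

* The boundary is the *euploid/aneuploid* midpoint for every magnitude,
  not the midpoint toward the next level: for a true +2 at 1× depth the
  latter sits at ≈0.83 expected consistency, statistically inseparable
  from the 0.8 cutoff, and randomly vetoes correct calls. Against the
  euploid boundary, true calls of any magnitude have expected consistency
  ≥ 0.85 and false local-artifact calls still fail.
* The veto is applied at the level of the call that is *used*: chromosome-
  wide consistency when the arms agree (a short arm of ~280 windows is
  noisy enough to dip below 0.8 about 0.6% of the time, and must not be
  able to break a correct whole-chromosome call into a spurious segmental
  one), per-arm consistency only when arm calls replace the whole call.
  The stand-alone arm-calling function retains per-arm downgrading for
  users who call arms directly.

idxstats-style input (per-chromosome totals only) supports whole-chromosome
calling with no arm calls or consistency checks.

## Population statistics

* **Gain vs loss**: exact binomial test with success probability 0.5,
  two-sided in the minimum-likelihood sense (sum of masses ≤ the observed
  outcome's mass). On the bundled table's simple-aneuploidy counts
  (49 gains vs 35 losses) this gives p = 0.156; on the compound-category
  counts 58 vs 20 it gives p = 1.95e-05. Compound-category gain/loss counts
  are reported under two conventions (individuals involved, chromosome-level
  events) because the aggregation convention behind published compound
  counts is not recoverable; the test itself takes counts as given.
* **Exact Poisson test**: two-sided by mass summation, with the same
  minimum-likelihood convention and a 1e-7 tie guard; implemented directly
  since no installed library exposes it.
* **Propensity**: per-chromosome event counts are compared against an
  empirical null of `n_perm` × 12 Poisson draws with rate equal to the mean
  observed count. Thresholds are the pooled nearest-rank 95th/5th
  percentiles (an alternative using per-permutation extrema is available,
  as is a zero-truncated null). *Prone* = observed strictly above the upper
  threshold; *resistant* = strictly below the lower. Defaults: 10,000
  permutations, plain (non-truncated) Poisson, pooled percentiles. On the
  bundled table this classifies chromosomes 1 and 3 resistant and 4, 9, 11
  prone in the combined gain+loss category. Because the rate is estimated
  from the 12 counts themselves and the null is discrete, per-chromosome
  per-side false-flag rates on null data run above the nominal 5% (up to
  ~10–12%); the calibration test asserts that band rather than 5%.
* **Reciprocal-cross bias**: Pearson chi-squared (1 df) on the 2×2
  aneuploid/euploid × cross-direction table, continuity correction off by
  default. The pipeline reports the computed statistic and p-value.
* **Factor correlations**: Pearson r with the two-sided t-distribution
  p-value on 12 paired observations. Gene counts and inter-chromosomal
  link counts are inputs supplied by the user; the bundled chromosome
  table ships without them (no curated per-chromosome values are bundled),
  and the correlation is exercised against synthetic factors in tests.

## Phenotype statistics

Euploid-vs-aneuploid comparison: per-trait two-sample t test,
pooled-variance Student's by default (the variant is not dictated by the
analysis being reproduced; Welch is a flag), traits with fewer than two
observations per group skipped with a warning. The karyotype-specific
screen regresses each trait on a karyotype-group indicator plus cross
direction as a fixed covariate over euploids + group members, for every
karyotype with ≥ 3 individuals, with Benjamini–Hochberg adjustment across
all (karyotype, trait) pairs. This is a deliberately plain fixed-covariate
linear-model screen — it shares the ≥3-member retention rule with a full
fixed-and-random-effect association scan but none of its machinery, and is
labeled as such; pedigree random effects are out of scope.

## Problem sizes and defaults

| quantity | default | note |
| --- | --- | --- |
| window size | 10 kb | ~37k windows on the bundled genome |
| read length | 125 bp | one count per read |
| calibration depth | 1× haploid | ~3.0M reads per individual |
| threshold replicates | 3 | averaged per chromosome/direction |
| recovery population | 200 individuals | study karyotype frequencies |
| permutations | 10,000 | propensity null |
| trait population | 312 | 21 traits, ~40% aneuploid |

The bundled genome uses the real rice chromosome lengths with approximate
centromere midpoints; no result depends on the exact values, and all
recovery properties hold for any valid 12-chromosome genome specification.

## Known limitations

Calling assumes fewer than six altered chromosomes (median baseline),
|δ| ≤ 2, and a single constitutive karyotype per plant. Sub-arm
breakpoints are not discovered; an event smaller than an arm dilutes the
arm statistic. Real-data coverage biases (GC, mappability, subgenome CNVs)
are not simulated, so the recovery rates reported here are upper bounds
for real libraries. The phenotype screen's effect estimates are
group-mean differences, not heritability-aware effects.
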