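"""Aneuploidy calling: threshold crossing, arm logic, consistency checks."""

import numpy as np
import pytest

from karyodepth.caller import (
    CONSISTENCY_CUTOFF,
    call_from_chromosome_counts,
    call_individual,
    call_whole_chromosomes,
)
from karyodepth.karyotype import EUPLOID, Karyotype, format_karyotype, parse_karyotype
from karyodepth.profiles import DepthProfile
from karyodepth.simulate import SimConfig, simulate_profile
from karyodepth.thresholds import NormalizedCoverage, normalized_coverage


def make_nc(values):
    values = np.asarray(values, dtype=float)
    return NormalizedCoverage("t", values / values.mean(), values, 100.0)


class TestWholeChromosomeCalls:
    def test_unit_values_are_euploid(self, rice_exact_thresholds):
        deltas = call_whole_chromosomes(make_nc([1.0] * 12), rice_exact_thresholds)
        assert not deltas.any()

    def test_value_exactly_on_threshold_is_called(self, rice_exact_thresholds):
        # Median of the raw vector is 1, so the rebaselined value of
        # chromosome 5 equals the gain threshold exactly; the inclusive
        # comparison must call it.
        values = [1.0] * 12
        values[4] = 60 / 49
        deltas = call_whole_chromosomes(make_nc(values), rice_exact_thresholds)
        assert deltas[4] == 1

    def test_double_gain_assigned_nearest_level(self, rice_genome, rice_thresholds):
        cfg = SimConfig(genome=rice_genome, seed=21)
        p = simulate_profile(parse_karyotype("+2 Chr. 10"), cfg)
        nc = normalized_coverage(p, rice_genome)
        deltas = call_whole_chromosomes(nc, rice_thresholds)
        assert deltas[9] == 2
        assert np.count_nonzero(deltas) == 1

    def test_seeded_single_gain_recovered(self, rice_genome, rice_thresholds):
        cfg = SimConfig(genome=rice_genome, seed=22)
        p = simulate_profile(parse_karyotype("+1 Chr. 09"), cfg)
        deltas = call_whole_chromosomes(
            normalized_coverage(p, rice_genome), rice_thresholds
        )
        assert deltas[8] == 1 and np.count_nonzero(deltas) == 1

    def test_compound_gains_survive_mean_normalization(self, rice_genome, rice_thresholds):
        # Three gained chromosomes drag the mean up; the median rebaseline
        # must keep all three above the gain threshold.
        cfg = SimConfig(genome=rice_genome, seed=23)
        p = simulate_profile(parse_karyotype("+1Chr04; +1Chr07; +1Chr11"), cfg)
        deltas = call_whole_chromosomes(
            normalized_coverage(p, rice_genome), rice_thresholds
        )
        assert list(np.nonzero(deltas)[0] + 1) == [4, 7, 11]
        assert all(deltas[[3, 6, 10]] == 1)

    def test_monotone_in_true_dosage(self, rice_genome, rice_thresholds):
        calls = []
        for delta in (-2, -1, 0, 1, 2):
            k = Karyotype.from_deltas(whole={5: delta})
            p = simulate_profile(k, SimConfig(genome=rice_genome, seed=30 + delta))
            deltas = call_whole_chromosomes(
                normalized_coverage(p, rice_genome), rice_thresholds
            )
            calls.append(deltas[4])
        assert calls == sorted(calls)
        assert calls == [-2, -1, 0, 1, 2]


class TestArmCalls:
    @pytest.mark.parametrize(
        "text",
        ["- 1L Chr. 11", "+ 1S Chr. 11", "+2S Chr. 10", "+2L Chr. 05; + 1 Chr. 09"],
    )
    def test_segmental_karyotypes_recovered(self, rice_genome, rice_thresholds, text):
        import zlib

        k = parse_karyotype(text)
        p = simulate_profile(k, SimConfig(genome=rice_genome, seed=zlib.crc32(text.encode())))
        call = call_individual(p, rice_genome, rice_thresholds)
        assert call.karyotype == k
        assert call.classification.is_segmental

    def test_euploid_profile_has_no_arm_calls(self, rice_genome, rice_thresholds):
        p = simulate_profile(EUPLOID, SimConfig(genome=rice_genome, seed=40))
        call = call_individual(p, rice_genome, rice_thresholds)
        assert call.karyotype == EUPLOID
        assert call.consistency == {}

    def test_short_arm_too_small_warns_instead_of_calling(
        self, rice_thresholds
    ):
        from conftest import make_genome

        # 20-kb short arm = 2 windows on chromosome 9: below the minimum
        g = make_genome(scale=100_000)
        g = type(g)(
            chromosomes=tuple(
                c if c.id != 9 else type(c)(
                    id=9, length=c.length, centromere=20_000,
                    relative_size=c.relative_size,
                )
                for c in g.chromosomes
            ),
            window_size=g.window_size,
        )
        cfg = SimConfig(genome=g, mean_depth=30.0, seed=41)
        p = simulate_profile(EUPLOID, cfg)
        call = call_individual(p, g, rice_thresholds)
        assert any("too short" in w for w in call.warnings)
        assert call.karyotype == EUPLOID

    def test_inconsistent_windows_downgrade_call(self, small_genome, rice_exact_thresholds):
        # Half the windows of chromosome 2 at dosage ratio 1.6, half at
        # 1.0: the chromosome-level value crosses the gain threshold but
        # only ~50% of windows sit on the gained side, far below the 0.8
        # consistency cutoff, so the call must be downgraded to no-call.
        wt = small_genome.windows()
        counts = wt.lengths.astype(float) * 10
        idx = np.where(wt.chrom == 2)[0]
        counts[idx[::2]] *= 1.6
        p = DepthProfile("mix", wt.chrom, wt.start, wt.end, counts)
        call = call_individual(p, small_genome, rice_exact_thresholds)
        assert call.karyotype.whole[1] == 0
        assert any("downgraded" in w for w in call.warnings)


class TestCallIndividual:
    def test_hidden_compound_classified(self, rice_genome, rice_thresholds):
        k = parse_karyotype("+ 1 Chr. 01; - 1 Chr. 10")
        p = simulate_profile(k, SimConfig(genome=rice_genome, seed=50))
        call = call_individual(p, rice_genome, rice_thresholds)
        assert call.karyotype == k
        assert call.classification.category == "compound"
        assert call.classification.is_hidden
        assert call.classification.chromosome_number == 48

    def test_consistency_fractions_high_for_true_calls(self, rice_genome, rice_thresholds):
        p = simulate_profile(
            parse_karyotype("+1 Chr. 11"), SimConfig(genome=rice_genome, seed=51)
        )
        call = call_individual(p, rice_genome, rice_thresholds)
        assert call.consistency[(11, "whole")] > CONSISTENCY_CUTOFF

    def test_values_mean_is_one(self, rice_genome, rice_thresholds):
        p = simulate_profile(
            parse_karyotype("-1 Chr. 04"), SimConfig(genome=rice_genome, seed=52)
        )
        call = call_individual(p, rice_genome, rice_thresholds)
        assert np.isclose(call.values.mean(), 1.0, atol=1e-12)


class TestChromosomeCountCalls:
    def test_idxstats_mode_recovers_whole_chromosome_changes(
        self, rice_genome, rice_exact_thresholds
    ):
        lengths = rice_genome.lengths.astype(float)
        counts = lengths / 125.0
        counts[8] *= 1.25  # one extra copy of chromosome 9
        call = call_from_chromosome_counts(
            "idx", counts, rice_genome, rice_exact_thresholds
        )
        assert format_karyotype(call.karyotype) == "+1Chr09"

    def test_rejects_wrong_shape(self, rice_genome, rice_exact_thresholds):
        with pytest.raises(ValueError):
            call_from_chromosome_counts(
                "bad", np.ones(11), rice_genome, rice_exact_thresholds
            )
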