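"""Caller criteria: switch counting, the six criteria, cohort verdicts."""

import numpy as np
import pytest

from shatterscan.datamodel import (
    BreakEnd,
    ConfigurationError,
    CriteriaConfig,
    GenomicInterval,
    SVJoin,
    ValidationError,
)
from shatterscan import caller as ca
from shatterscan.caller import (
    call_cohort,
    count_state_changes,
    exact_multinomial_gof,
    null_ks_distribution,
    score_chromosome,
    snpa_criterion,
    walk_derivative,
)
from shatterscan.simulate import (
    CHROM_LENGTHS,
    ShatterConfig,
    shatter_chromosome,
    simulate_cohort,
)

from conftest import make_profile


class TestCountStateChanges:
    def test_all_diploid(self, diploid_profile):
        assert count_state_changes(diploid_profile, "3") == (0, 1, None)

    def test_absent_chromosome(self, diploid_profile):
        assert count_state_changes(diploid_profile, "19") == (0, 1, None)

    def test_alternating_21_segments(self, alternating_profile):
        n_switches, n_states, span = count_state_changes(alternating_profile, "3")
        assert n_switches == 20
        assert n_states == 2

    def test_cnloh_transitions_not_counted(self):
        prof = make_profile("c", "1", [2, (2, True), 2])
        assert count_state_changes(prof, "1")[0] == 0

    def test_isolated_deletion_scores_two(self):
        prof = make_profile("c", "1", [2, (1, True), 2])
        n_switches, n_states, span = count_state_changes(prof, "1")
        assert (n_switches, n_states) == (2, 2)
        assert span.width == 1_000_000


class TestSnpaCriterion:
    def test_twenty_switch_profile_flagged(self, alternating_profile):
        assert snpa_criterion(alternating_profile, "3").is_cth

    def test_nine_switches_not_flagged(self):
        # 2,1 alternation with 9 transitions
        states = [2 if i % 2 == 0 else 1 for i in range(10)]
        prof = make_profile("c", "1", states)
        call = snpa_criterion(prof, "1")
        assert call.n_switches == 9
        assert not call.is_cth

    def test_four_states_not_flagged(self):
        # 12+ switches cycling through 4 distinct cn values
        states = [0, 1, 3, 4] * 4
        prof = make_profile("c", "1", states)
        call = snpa_criterion(prof, "1")
        assert call.n_switches >= 12
        assert call.n_states > 3
        assert not call.is_cth

    def test_threshold_sharpness(self):
        """Exactly min_switches-1 never flags; exactly min_switches
        with <= max_states always does."""
        for n_switch in (9, 10):
            states = [2 if i % 2 == 0 else 1 for i in range(n_switch + 1)]
            prof = make_profile("c", "1", states)
            call = snpa_criterion(prof, "1")
            assert call.n_switches == n_switch
            assert call.is_cth is (n_switch >= 10)

    def test_monotonicity_distant_diploid_segment_is_inert(self, alternating_profile):
        """Appending a far-away diploid, non-LOH segment never changes
        the verdict."""
        from shatterscan.datamodel import Segment, SegmentProfile

        base = snpa_criterion(alternating_profile, "3")
        segs = [s for s in alternating_profile.segments["3"]]
        segs.append(Segment(GenomicInterval("3", 90_000_000, 95_000_000), 2, False))
        extended = SegmentProfile.from_segments("alt", segs)
        call = snpa_criterion(extended, "3")
        assert (call.is_cth, call.n_switches, call.n_states) == (
            base.is_cth, base.n_switches, base.n_states,
        )


class TestBreakpointClustering:
    def test_clustered_breakpoints_pass(self, rng):
        # 20 breakpoints confined to 10% of the chromosome
        bp = rng.uniform(0, 10_000_000, size=20)
        p, ok = ca.test_breakpoint_clustering(bp, 100_000_000, rng=rng)
        assert ok and p < 0.01

    def test_two_breakpoints_fail_at_p1(self):
        p, ok = ca.test_breakpoint_clustering([5, 10], 100, )
        assert (p, ok) == (1.0, False)

    def test_uniform_breakpoints_usually_retained(self, rng):
        bp = rng.uniform(0, 1e8, size=20)
        p, ok = ca.test_breakpoint_clustering(bp, 1e8, rng=rng)
        assert p > 0.01 and not ok  # deterministic for this seed

    def test_invalid_chromosome_length(self):
        with pytest.raises(ValidationError):
            ca.test_breakpoint_clustering([1, 2, 3], 0)


class TestOscillation:
    def test_oscillating_two_state_profile_passes(self, alternating_profile):
        assert ca.test_oscillation(alternating_profile, "3")

    def test_four_state_profile_fails(self):
        prof = make_profile("c", "1", [0, 1, 3, 4] * 4)
        assert not ca.test_oscillation(prof, "1")

    def test_diploid_fails(self, diploid_profile):
        assert not ca.test_oscillation(diploid_profile, "3")


class TestLohInterspersion:
    def test_three_alternations_pass(self):
        prof = make_profile(
            "c", "1", [(1, True), (2, False), (1, True), (2, False)]
        )
        assert ca.test_loh_interspersion(prof, "1")

    def test_no_loh_fails(self):
        prof = make_profile("c", "1", [2, 1, 2, 1, 2])
        # cn=1 without LOH flags nowhere: alternations depend on flags only
        assert not ca.test_loh_interspersion(prof, "1")

    def test_simulator_positive_passes_in_most_seeds(self):
        n_pass = 0
        for seed in range(50):
            cfg = ShatterConfig(chrom="7", n_fragments=25, loss_prob=0.4,
                                loh_fraction=0.5, seed=seed,
                                region_span_bp=80_000_000)
            prof, _, _ = shatter_chromosome(cfg)
            n_pass += ca.test_loh_interspersion(prof, "7")
        assert n_pass >= 45  # >= 90% of seeds


class TestSingleAllele:
    def test_all_one_haplotype_passes(self):
        joins = [
            SVJoin(BreakEnd("1", i, "head"), BreakEnd("1", i + 5, "tail"), haplotype="A")
            for i in range(0, 100, 10)
        ]
        ok, status = ca.test_single_allele(joins)
        assert ok and status == "ok"

    def test_balanced_haplotypes_fail(self):
        joins = [
            SVJoin(BreakEnd("1", i, "head"), BreakEnd("1", i + 5, "tail"),
                   haplotype="A" if i < 50 else "B")
            for i in range(0, 100, 10)
        ]
        ok, _ = ca.test_single_allele(joins)
        assert not ok

    def test_unlabeled_abstains(self):
        joins = [SVJoin(BreakEnd("1", 1, "head"), BreakEnd("1", 9, "tail"))]
        ok, status = ca.test_single_allele(joins)
        assert not ok and status == "no data"


class TestJoinRandomness:
    def test_all_ht_rejected(self):
        counts = {"HT": 12}
        p, ok, status = ca.test_join_randomness(counts)
        assert not ok and p < 1e-5

    def test_perfectly_uniform_p1(self):
        p, ok, _ = ca.test_join_randomness({"HH": 3, "HT": 3, "TH": 3, "TT": 3})
        assert p == pytest.approx(1.0)
        assert ok

    def test_seven_joins_abstain(self):
        p, ok, status = ca.test_join_randomness({"HH": 7})
        assert not ok and status == "insufficient joins"

    def test_exact_tail_probability(self):
        # all 12 in one cell: only the 4 degenerate outcomes are as extreme
        p = exact_multinomial_gof([12, 0, 0, 0])
        assert p == pytest.approx(4 * 0.25**12, rel=1e-9)


class TestWalkDerivative:
    def _cycle(self, chrom, offset):
        """Two fragments joined into a closed cycle (2 joins)."""
        f1 = GenomicInterval(chrom, offset, offset + 10)
        f2 = GenomicInterval(chrom, offset + 20, offset + 30)
        joins = [
            SVJoin(BreakEnd(chrom, f1.end, "tail"), BreakEnd(chrom, f2.start, "head")),
            SVJoin(BreakEnd(chrom, f2.end, "tail"), BreakEnd(chrom, f1.start, "head")),
        ]
        return [f1, f2], joins

    def test_simulator_positive_walks_fully(self):
        for seed in range(10):
            cfg = ShatterConfig(chrom="7", n_fragments=15, loss_prob=0.4, seed=seed,
                                region_span_bp=60_000_000)
            _, joins, truth = shatter_chromosome(cfg)
            coverage, ok = walk_derivative(joins, truth.fragments["7"])
            assert coverage == 1.0 and ok

    def test_two_disconnected_cycles_cover_half(self):
        frags1, joins1 = self._cycle("1", 0)
        frags2, joins2 = self._cycle("1", 100)
        coverage, ok = walk_derivative(joins1 + joins2, frags1 + frags2,
                                       CriteriaConfig(walk_coverage=0.9))
        assert coverage == pytest.approx(0.5)
        assert not ok

    def test_zero_joins(self):
        coverage, ok = walk_derivative([], [GenomicInterval("1", 0, 10)])
        assert (coverage, ok) == (0.0, False)

    def test_reused_fragment_end_rejected(self):
        frag = [GenomicInterval("1", 0, 10), GenomicInterval("1", 20, 30),
                GenomicInterval("1", 40, 50)]
        joins = [
            SVJoin(BreakEnd("1", 10, "tail"), BreakEnd("1", 20, "head")),
            SVJoin(BreakEnd("1", 10, "tail"), BreakEnd("1", 40, "head")),
        ]
        with pytest.raises(ValidationError, match="used twice"):
            walk_derivative(joins, frag)


class TestScoreChromosome:
    def test_simulator_positive_full_mode(self):
        cfg = ShatterConfig(chrom="7", n_fragments=31, loss_prob=0.4,
                            region_span_bp=60_000_000, seed=5, loh_fraction=0.5)
        prof, joins, _ = shatter_chromosome(cfg)
        call = score_chromosome(prof, joins, "7", mode="full",
                                chrom_length=CHROM_LENGTHS["7"])
        assert call.is_cth
        assert call.n_criteria_met >= 3

    def test_diploid_genome_never_flagged(self, diploid_profile):
        for mode in ("snpa_only", "full"):
            call = score_chromosome(diploid_profile, [], "3", mode=mode)
            assert not call.is_cth

    def test_full_mode_without_joins_rejected(self, diploid_profile):
        with pytest.raises(ConfigurationError):
            score_chromosome(diploid_profile, None, "3", mode="full")

    def test_unknown_mode_rejected(self, diploid_profile):
        with pytest.raises(ConfigurationError):
            score_chromosome(diploid_profile, [], "3", mode="wgs")


class TestCallCohort:
    def test_empty_cohort(self):
        result = call_cohort([], {}, mode="snpa_only")
        assert result.calls == [] and result.case_verdicts == {}

    def test_duplicate_case_ids_rejected(self, diploid_profile):
        with pytest.raises(ValidationError, match="duplicate"):
            call_cohort([diploid_profile, diploid_profile])

    def test_flagged_chromosome_count_matches_truth(self):
        cohort = simulate_cohort(4, n_positives=1, cth_chrom_counts=(3,),
                                 master_seed=9)
        result = call_cohort(cohort.profiles, cohort.joins, mode="snpa_only")
        cid = cohort.params["positive_ids"][0]
        assert sorted(result.flagged_chromosomes[cid]) == sorted(
            cohort.truths[cid].cth_chromosomes
        )

    def test_verdict_iff_any_chromosome_flagged(self):
        cohort = simulate_cohort(6, n_positives=2, master_seed=2)
        result = call_cohort(cohort.profiles, cohort.joins, mode="snpa_only")
        for cid, verdict in result.case_verdicts.items():
            assert verdict == bool(result.flagged_chromosomes[cid])


def test_count_state_changes_brute_force_oracle(rng):
    """Adjacent-pair scan over an independently merged state list must
    agree with the caller on 1,000 random small profiles."""
    for _ in range(1000):
        n = int(rng.integers(1, 15))
        states = [
            (int(rng.integers(0, 4)), bool(rng.integers(0, 2))) for _ in range(n)
        ]
        prof = make_profile("r", "2", states)
        # oracle: merge equal adjacent states, find non-diploid window
        merged = []
        for s in states:
            if not merged or merged[-1] != s:
                merged.append(s)
        idx = [i for i, (cn, _) in enumerate(merged) if cn != 2]
        if not idx:
            expected = (0, 1)
        else:
            lo, hi = max(idx[0] - 1, 0), min(idx[-1] + 1, len(merged) - 1)
            window = merged[lo: hi + 1]
            expected = (
                sum(1 for a, b in zip(window, window[1:]) if a[0] != b[0]),
                len({cn for cn, _ in window}),
            )
        got = count_state_changes(prof, "2")
        assert (got[0], got[1]) == expected
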