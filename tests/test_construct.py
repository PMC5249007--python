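"""The sampling construction: free-end logic, maximal stage, completion."""

import numpy as np
import pytest

from antimedian.construct import (
    MAXIMAL,
    InfeasibleSampleError,
    SampleRequest,
    construct_antimedian,
    empirical_max_theta3,
    random_completion,
    sample_stage,
)
from antimedian.genome import PartialAssembly, validate_genome
from antimedian.metrics import overlap_profile, score, shared_adjacency_count
from antimedian.simulate import TrioSpec, random_genome, random_trio


class TestSampleStage:
    def test_theta_zero_is_noop(self, rng):
        g = random_genome(20, rng)
        asm = PartialAssembly.empty(20)
        out, added = sample_stage(asm, g, 0.0, rng)
        assert added == 0 and not out.adjacencies

    def test_maximal_from_empty_takes_everything(self, rng):
        g = random_genome(20, rng)
        out, added = sample_stage(PartialAssembly.empty(20), g, MAXIMAL, rng)
        assert added == 20 and out.adjacencies == set(g.adjacencies)

    def test_explicit_request_beyond_candidates_fails_loudly(self, rng):
        g = random_genome(10, rng)
        asm, _ = sample_stage(PartialAssembly.empty(10), g, MAXIMAL, rng)
        with pytest.raises(InfeasibleSampleError, match="achievable"):
            sample_stage(asm, g, 0.5, rng)

    def test_two_free_end_fraction_after_first_stage(
        self, zero_overlap_trio_10k
    ):
        """After sampling theta1 = 0.15 from g1, the fraction of g2
        adjacencies with both ends free is close to (1 - 0.15)^2."""
        g1, g2, _ = zero_overlap_trio_10k
        rng = np.random.default_rng(3)
        asm, _ = sample_stage(PartialAssembly.empty(g1.n), g1, 0.15, rng)
        frac = sum(asm.is_free(a) for a in g2.adjacencies) / g2.n
        assert frac == pytest.approx((1 - 0.15) ** 2, abs=0.02)


class TestRandomCompletion:
    def test_no_free_ends_is_identity(self, rng):
        g = random_genome(15, rng)
        asm = PartialAssembly.from_adjacencies(g.adjacencies, 15)
        assert random_completion(asm, rng).adjacencies == g.adjacencies

    def test_two_free_ends_forced(self, rng):
        asm = PartialAssembly.from_adjacencies([(0, 2)], 2)
        g = random_completion(asm, rng)
        assert g.adjacencies == frozenset({(0, 2), (1, 3)})

    def test_completion_of_empty_assembly_scores_three(
        self, zero_overlap_trio_10k
    ):
        x = random_completion(
            PartialAssembly.empty(10_000), np.random.default_rng(6)
        )
        assert score(x, *zero_overlap_trio_10k) == pytest.approx(3.0, abs=0.01)

    def test_preserves_assembly_and_is_valid(self, rng):
        g = random_genome(40, rng)
        asm, _ = sample_stage(PartialAssembly.empty(40), g, 0.3, rng)
        kept = set(asm.adjacencies)
        x = random_completion(asm, rng)
        validate_genome(x.adjacencies, 40)
        assert kept <= set(x.adjacencies)


class TestConstructAntimedian:
    def test_conservation_of_adjacency_counts(self):
        """sampled + overlap + randomly completed always sum to n."""
        trio = random_trio(
            TrioSpec(n=500, psi=0.1, omega12=0.06, omega13=0.04,
                     omega23=0.02, seed=9)
        )
        rng = np.random.default_rng(10)
        res = construct_antimedian(
            *trio, SampleRequest(0.1, 0.1, MAXIMAL), rng
        )
        n = 500
        ov = res.realized_overlaps
        n_overlap = round(n * (ov.psi + ov.omega12 + ov.omega13 + ov.omega23))
        n_sampled = round(n * sum(res.realized_theta))
        assert n_overlap + n_sampled + res.n_random_completed == n

    def test_result_score_consistent(self, zero_overlap_trio_10k):
        rng = np.random.default_rng(0)
        res = construct_antimedian(
            *zero_overlap_trio_10k, SampleRequest(0.2, 0.2), rng
        )
        assert res.score == score(res.genome, *zero_overlap_trio_10k)

    def test_all_zero_thetas_give_random_genome(self, zero_overlap_trio_10k):
        rng = np.random.default_rng(4)
        res = construct_antimedian(
            *zero_overlap_trio_10k, SampleRequest(0.0, 0.0, 0.0), rng
        )
        assert res.score == pytest.approx(3.0, abs=0.01)

    def test_full_overlap_returns_the_common_genome(self):
        trio = random_trio(TrioSpec(n=60, psi=1.0, seed=3))
        rng = np.random.default_rng(1)
        res = construct_antimedian(*trio, SampleRequest(0.0, 0.0), rng)
        assert res.genome.adjacencies == trio[0].adjacencies
        assert res.score == 0.0

    def test_overlap_adjacencies_always_included(self):
        trio = random_trio(
            TrioSpec(n=200, psi=0.15, omega12=0.1, omega13=0.05, seed=6)
        )
        g1, g2, g3 = trio
        required = (
            (g1.adjacencies & g2.adjacencies)
            | (g1.adjacencies & g3.adjacencies)
            | (g2.adjacencies & g3.adjacencies)
        )
        res = construct_antimedian(
            *trio, SampleRequest(0.1, 0.1), np.random.default_rng(2)
        )
        assert required <= res.genome.adjacencies

    def test_completion_adds_no_shared_adjacencies(self, zero_overlap_trio_10k):
        """Random completion contributes O(1), not O(n), to shared counts."""
        rng = np.random.default_rng(5)
        res = construct_antimedian(
            *zero_overlap_trio_10k, SampleRequest(0.15, 0.15), rng
        )
        n = res.n
        for g, theta in zip(zero_overlap_trio_10k, res.realized_theta):
            excess = shared_adjacency_count(res.genome, g) - round(n * theta)
            assert excess / n < 0.01

    def test_realized_maximal_theta3_monotone_in_theta1(self):
        """More sampled from g1 leaves fewer free ends for g3."""
        trio = random_trio(TrioSpec(n=2000, seed=14))
        means = []
        for t1 in (0.0, 0.1, 0.2, 0.3, 0.4):
            stats = empirical_max_theta3(
                *trio, t1, 0.1, np.random.default_rng(8), replicates=2
            )
            means.append(stats.theta3_mean)
        assert all(a >= b - 0.01 for a, b in zip(means, means[1:]))


class TestEmpiricalMaxTheta3:
    def test_nothing_sampled_keeps_all_of_g3(self):
        trio = random_trio(TrioSpec(n=1000, seed=21))
        stats = empirical_max_theta3(
            *trio, 0.0, 0.0, np.random.default_rng(0), replicates=2
        )
        assert stats.theta3_mean == pytest.approx(1.0, abs=0.01)

    def test_table_value_at_035_035(self, zero_overlap_trio_10k):
        stats = empirical_max_theta3(
            *zero_overlap_trio_10k, 0.35, 0.35,
            np.random.default_rng(30), replicates=3,
        )
        assert stats.theta3_mean == pytest.approx(0.09, abs=0.02)

    def test_general_overlap_reported_against_both_closed_forms(self):
        """With an asymmetric overlap structure the two candidate closed
        forms for max theta3 differ; the simulation lands on the one that
        conditions on g3's own shared ends."""
        from antimedian.analytic import max_theta3

        ov = dict(psi=0.1, omega12=0.2, omega13=0.05, omega23=0.05)
        trio = random_trio(TrioSpec(n=5000, seed=17, **ov))
        profile = overlap_profile(*trio)
        stats = empirical_max_theta3(
            *trio, 0.1, 0.1, np.random.default_rng(18), replicates=3
        )
        stationary = max_theta3(0.1, 0.1, profile, model="stationary")
        conditional = max_theta3(0.1, 0.1, profile, model="conditional")
        dev_s = abs(stats.theta3_mean - stationary)
        dev_c = abs(stats.theta3_mean - conditional)
        assert dev_c < 0.02
        assert dev_c < dev_s  # the forms genuinely differ here
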