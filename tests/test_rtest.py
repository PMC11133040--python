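import math

import numpy as np
import pytest

from scedrand import (
    ABABScheme,
    ABStartScheme,
    ATDScheme,
    EffectSpec,
    MultipleBaselineScheme,
    ResponseFunction,
    SCEDSeries,
    adjust_pvalues,
    orient_scores,
    p_value,
    pearson_statistic,
    randomization_distribution,
    scan_durations,
    scan_latencies,
)
from scedrand.errors import DesignInconsistencyError
from scedrand.rtest import TestResult as RandTestResult
from scedrand.schemes import ATDDivision
from scedrand.simulate import GenerationModel, generate_series

# Frozen oracle value for the published worked example: scipy.stats.pearsonr
# and R cor() both give 0.9996406 for these ten pairs.
WORKED_EXAMPLE_R = 0.9996405988943752


def naive_pearson(x, y):
    """Textbook formula, written independently of the library."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def make_ab_series(scores, n_A):
    scores = np.asarray(scores, dtype=float)
    labels = ("A",) * n_A + ("B",) * (len(scores) - n_A)
    return SCEDSeries(labels=labels, scores=scores)


class TestPearsonStatistic:
    def test_nonlinear_worked_example(self):
        scores = np.array([3, 3, 3, 3, 3, 7, 13, 25, 49, 97], float)
        rf = ResponseFunction(values=np.array([0, 0, 0, 0, 0, 2, 4, 8, 16, 32], float))
        r = pearson_statistic(scores, rf)
        assert r == pytest.approx(WORKED_EXAMPLE_R, abs=1e-12)
        assert r == pytest.approx(naive_pearson(scores, rf.values), abs=1e-12)

    def test_perfect_correlation_and_anticorrelation(self):
        rf = ResponseFunction(values=np.array([0, 0, 1, 2, 3.0]))
        assert pearson_statistic(rf.values.copy(), rf) == pytest.approx(1.0)
        assert pearson_statistic(-rf.values, rf) == pytest.approx(-1.0)

    def test_constant_inputs_conventioned_to_zero(self):
        rf = ResponseFunction(values=np.zeros(4))
        assert pearson_statistic(np.array([1, 2, 3, 4.0]), rf) == 0.0
        rf2 = ResponseFunction(values=np.array([0, 0, 1, 1.0]))
        assert pearson_statistic(np.full(4, 7.0), rf2) == 0.0

    def test_statistic_uses_only_included_occasions(self):
        rf = ResponseFunction(
            values=np.array([9, 0, 0, 1, 1, 9.0]),
            mask=np.array([False, True, True, True, True, False]),
        )
        scores = np.array([999.0, 0, 0, 5, 5, -999.0])
        assert pearson_statistic(scores, rf) == pytest.approx(1.0)

    def test_affine_invariance_of_response_function(self, rng):
        scores = rng.normal(size=10)
        base = np.array([0, 0, 0, 0, 1, 2, 3, 3, 3, 3.0])
        r0 = pearson_statistic(scores, ResponseFunction(values=base))
        r_pos = pearson_statistic(scores, ResponseFunction(values=2.5 * base + 7))
        r_neg = pearson_statistic(scores, ResponseFunction(values=-1.5 * base + 2))
        assert r_pos == pytest.approx(r0, abs=1e-12)
        assert r_neg == pytest.approx(-r0, abs=1e-12)


class TestOrientScores:
    def test_increase_is_identity(self):
        assert orient_scores([1, 2, 3], "increase").tolist() == [1, 2, 3]

    def test_decrease_negates(self):
        assert orient_scores([1, 2, 3], "decrease").tolist() == [-1, -2, -3]

    def test_decrease_flips_statistic_sign(self, step_series):
        rf = ResponseFunction(values=np.array([0, 0, 0, 1, 1, 1.0]))
        r_inc = pearson_statistic(orient_scores(step_series.scores, "increase"), rf)
        r_dec = pearson_statistic(orient_scores(step_series.scores, "decrease"), rf)
        assert r_dec == pytest.approx(-r_inc)


class TestPValue:
    def make_result(self, pseudovalues, observed_index):
        return RandTestResult(
            r_obs=pseudovalues[observed_index],
            pseudovalues=np.array(pseudovalues, float),
            observed_index=observed_index,
            divisions=tuple(range(len(pseudovalues))),
            degenerate_divisions=(),
        )

    def test_strictly_largest_of_six(self):
        res = self.make_result([0.9, 0.5, 0.1, -0.2, 0.0, 0.3], 0)
        assert p_value(res) == pytest.approx(1 / 6)
        assert res.rank == 1

    def test_ties_count_as_extreme(self):
        res = self.make_result([0.9, 0.9, 0.2, 0.1], 0)
        assert p_value(res) == pytest.approx(2 / 4)

    def test_complete_ties_give_p_one(self):
        res = self.make_result([0.4, 0.4, 0.4], 1)
        assert p_value(res) == 1.0

    def test_p_support_is_multiples_of_one_over_m(self, rng):
        for _ in range(20):
            vals = rng.normal(size=7).tolist()
            res = self.make_result(vals, int(rng.integers(7)))
            assert res.p * res.m == pytest.approx(round(res.p * res.m))
            assert res.p >= res.min_p


class TestRandomizationDistribution:
    def test_perfect_step_ranks_first(self, step_series, immediate_abrupt):
        scheme = ABStartScheme(n=6, min_A=2, min_B=2)
        res = randomization_distribution(step_series, scheme, immediate_abrupt)
        assert res.m == 3
        assert res.rank == 1
        assert res.r_obs == pytest.approx(1.0)
        # brute-force the three correlations independently
        for stat, n_A in zip(res.pseudovalues, (2, 3, 4)):
            rf = [0.0] * n_A + [1.0] * (6 - n_A)
            assert stat == pytest.approx(naive_pearson(step_series.scores, rf))

    def test_pseudovalues_match_naive_enumeration(self, rng):
        """Brute-force oracle over all AB series with n <= 10."""
        spec = EffectSpec(progression="gradual")
        for n in range(6, 11):
            scores = rng.normal(size=n)
            n_A_true = int(rng.integers(2, n - 2))
            series = make_ab_series(scores, n_A_true)
            scheme = ABStartScheme(n=n, min_A=2, min_B=2)
            res = randomization_distribution(series, scheme, spec)
            expected = []
            for a in range(2, n - 1):
                rf = [0.0] * a + [float(j) for j in range(1, n - a + 1)]
                expected.append(naive_pearson(scores, rf))
            assert res.pseudovalues == pytest.approx(expected)
            assert res.r_obs == pytest.approx(expected[n_A_true - 2])

    def test_degenerate_division_flagged_not_dropped(self):
        # latest admissible start leaves n_B = 2 <= latency
        series = make_ab_series(np.arange(10.0), 4)
        scheme = ABStartScheme(n=10, min_A=2, min_B=2)
        spec = EffectSpec(onset="delayed", latency=2)
        res = randomization_distribution(series, scheme, spec)
        assert res.m == 7
        degenerate_starts = {d.start for d in res.degenerate_divisions}
        assert degenerate_starts == {9}  # n_A=8 leaves only the latency
        idx = [d.start for d in res.divisions].index(9)
        assert res.pseudovalues[idx] == 0.0

    def test_observed_division_must_be_admissible(self, step_series, immediate_abrupt):
        scheme = ABStartScheme(n=6, min_A=4, min_B=1)
        with pytest.raises(DesignInconsistencyError):
            randomization_distribution(step_series, scheme, immediate_abrupt)

    def test_two_sided_ranks_by_magnitude(self, immediate_abrupt):
        series = make_ab_series([5, 5, 5, 0, 0, 0.0], 3)  # strong *negative* r
        scheme = ABStartScheme(n=6, min_A=2, min_B=2)
        one = randomization_distribution(series, scheme, immediate_abrupt)
        two = randomization_distribution(
            series, scheme, immediate_abrupt, two_sided=True
        )
        assert one.r_obs == pytest.approx(-1.0)
        assert one.p == 1.0
        assert two.rank == 1
        assert not one.favorable

    def test_decrease_aim_mirrors_increase(self, immediate_abrupt):
        series = make_ab_series([5, 5, 5, 0, 0, 0.0], 3)
        scheme = ABStartScheme(n=6, min_A=2, min_B=2)
        res = randomization_distribution(
            series, scheme, immediate_abrupt.with_(aim="decrease")
        )
        assert res.r_obs == pytest.approx(1.0)
        assert res.rank == 1
        assert res.favorable


class TestMeanDifferenceEquivalence:
    """With a binary response function the statistic is the point-biserial
    correlation, which is p-value-equivalent to a mean difference whenever
    the division does not change the group sizes (r = diff * sqrt(nA*nB) /
    (n*s), and sqrt(nA*nB) is constant across such divisions).  Block-
    randomized alternation designs enumerate exactly that situation."""

    def naive_mean_diff_pvalues(self, scores, divisions):
        stats = []
        for labels in divisions:
            b_vals = [s for s, l in zip(scores, labels) if l == "B"]
            a_vals = [s for s, l in zip(scores, labels) if l == "A"]
            stats.append(sum(b_vals) / len(b_vals) - sum(a_vals) / len(a_vals))
        return [
            sum(1 for s in stats if s >= obs) / len(stats) for obs in stats
        ]

    @pytest.mark.parametrize("b", [2, 3, 4, 5, 6])
    def test_p_equivalence_on_full_atd_enumeration(self, rng, b):
        from scedrand import enumerate_divisions

        scheme = ATDScheme(b=b)
        scores = rng.normal(size=2 * b)
        divisions = enumerate_divisions(scheme)
        md_ps = self.naive_mean_diff_pvalues(
            scores.tolist(), [d.labels for d in divisions]
        )
        for i, d in enumerate(divisions):
            series = SCEDSeries(labels=d.labels, scores=scores)
            res = randomization_distribution(series, scheme, EffectSpec())
            assert res.p == pytest.approx(md_ps[i])


class TestMultiComparisonDesigns:
    def test_multiple_baseline_mean_of_tier_correlations(self):
        scheme = MultipleBaselineScheme(variant="WW", t=2, start_points=(3, 5))
        spec = EffectSpec()
        tiers = [
            make_ab_series([0, 0, 5, 5, 5, 5.0], 2),   # starts at 3
            make_ab_series([0, 0, 0, 0, 5, 5.0], 4),   # starts at 5
        ]
        res = randomization_distribution(tiers, scheme, spec)
        assert res.m == 2
        assert res.rank == 1
        assert res.r_obs == pytest.approx(1.0)  # both tiers correlate perfectly
        # the swapped assignment misplaces both steps, statistic < 1
        other = res.pseudovalues[1 - res.observed_index]
        assert other < 1.0
        # cross-check: mean of naive per-tier correlations for the swap
        r1 = naive_pearson([0, 0, 5, 5, 5, 5.0], [0, 0, 0, 0, 1, 1.0])
        r2 = naive_pearson([0, 0, 0, 0, 5, 5.0], [0, 0, 1, 1, 1, 1.0])
        assert other == pytest.approx((r1 + r2) / 2)

    def test_abab_mean_over_phase_pairs(self):
        scheme = ABABScheme(n=12, I=4, k=3)
        labels = ("A",) * 3 + ("B",) * 3 + ("A",) * 3 + ("B",) * 3
        scores = np.array([0, 0, 0, 5, 5, 5, 0, 0, 0, 5, 5, 5.0])
        series = SCEDSeries(labels=labels, scores=scores)
        res = randomization_distribution(series, scheme, EffectSpec())
        assert res.m == 1
        assert res.r_obs == pytest.approx(1.0)

    def test_atd_observed_sequence(self):
        scheme = ATDScheme(b=3)
        labels = ("A", "B", "B", "A", "A", "B")
        scores = np.array([0, 5, 5, 0, 0, 5.0])
        series = SCEDSeries(labels=labels, scores=scores)
        res = randomization_distribution(series, scheme, EffectSpec())
        assert res.m == 8
        assert res.rank == 1
        assert res.r_obs == pytest.approx(1.0)
        # the mirrored sequence is perfectly anticorrelated
        mirrored = ATDDivision(labels=("B", "A", "A", "B", "B", "A"))
        idx = res.divisions.index(mirrored)
        assert res.pseudovalues[idx] == pytest.approx(-1.0)


class TestScans:
    def test_duration_scan_recovers_true_duration(self):
        shape = EffectSpec(duration="temporary", effect_duration=3)
        series = generate_series(
            GenerationModel(delta=1.0, sigma=0.0, shape=shape), 6, 8, seed=0
        )
        scheme = ABStartScheme(n=14, min_A=3, min_B=3)
        scan = scan_durations(series, scheme, EffectSpec(), d_max=5)
        r_by_axis = {ax: res.r_obs for ax, res in zip(scan.axis, scan.results)}
        assert max(r_by_axis, key=r_by_axis.get) == 3
        assert r_by_axis[3] == pytest.approx(1.0)
        d3 = scan.results[scan.axis.index(3)]
        assert d3.rank == 1

    def test_latency_scan_recovers_true_delay(self):
        shape = EffectSpec(onset="delayed", latency=2)
        series = generate_series(
            GenerationModel(delta=1.0, sigma=0.0, shape=shape), 6, 8, seed=0
        )
        scheme = ABStartScheme(n=14, min_A=3, min_B=3)
        scan = scan_latencies(series, scheme, EffectSpec(), L_max=5)
        r_by_axis = {ax: res.r_obs for ax, res in zip(scan.axis, scan.results)}
        assert max(r_by_axis, key=r_by_axis.get) == 2
        assert r_by_axis[2] == pytest.approx(1.0)

    def test_sustained_shift_ranks_first_for_all_durations(self):
        # a clear sustained level shift dominates every scenario
        series = generate_series(GenerationModel(delta=10.0, sigma=0.2), 9, 8, seed=4)
        scheme = ABStartScheme(n=17, min_A=4, max_A=10, min_B=8)
        scan = scan_durations(series, scheme, EffectSpec(), d_max=5)
        assert all(res.rank == 1 for res in scan.results)

    def test_duration_scan_truncates_with_warning(self, step_series):
        scheme = ABStartScheme(n=6, min_A=2, min_B=2)
        with pytest.warns(UserWarning, match="truncat"):
            scan = scan_durations(step_series, scheme, EffectSpec(), d_max=10)
        assert max(v for v in scan.axis if v is not None) == 3

    def test_latency_scan_truncates_with_warning(self, step_series):
        scheme = ABStartScheme(n=6, min_A=2, min_B=2)
        with pytest.warns(UserWarning, match="truncat"):
            scan = scan_latencies(step_series, scheme, EffectSpec(), L_max=5)
        assert scan.axis == (1, 2)

    def test_scan_reuses_identical_divisions(self, step_series):
        scheme = ABStartScheme(n=6, min_A=2, min_B=2)
        scan = scan_durations(step_series, scheme, EffectSpec(), d_max=2)
        for res in scan.results:
            assert res.divisions == scan.results[0].divisions


class TestAdjustPValues:
    def test_bonferroni_doubles_two_pvalues(self):
        assert adjust_pvalues([0.01, 0.04], "bonferroni").tolist() == pytest.approx(
            [0.02, 0.08]
        )

    def test_none_is_identity(self):
        ps = [0.3, 0.01, 0.7]
        assert adjust_pvalues(ps, "none").tolist() == ps

    def test_holm_step_down_hand_computed(self):
        # sorted (0.01, 0.03, 0.04) x (3, 2, 1) = (0.03, 0.06, 0.04),
        # running max -> (0.03, 0.06, 0.06), mapped back to input order
        out = adjust_pvalues([0.01, 0.04, 0.03], "holm")
        assert out.tolist() == pytest.approx([0.03, 0.06, 0.06])

    def test_adjusted_never_below_raw_and_capped(self, rng):
        ps = rng.uniform(size=8)
        for method in ("bonferroni", "holm"):
            adj = adjust_pvalues(ps, method)
            assert np.all(adj >= ps - 1e-12)
            assert np.all(adj <= 1.0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], "fdr")


class TestNullBehaviour:
    def test_rank_of_observed_is_uniform_under_null(self, rng):
        """With i.i.d. noise and a uniformly drawn start, every rank 1..m is
        equally likely; check frequencies within 3 binomial SEs."""
        scheme = ABStartScheme(n=12, min_A=2, min_B=2)
        spec = EffectSpec()
        m = 9
        reps = 1800
        counts = np.zeros(m)
        from scedrand import enumerate_divisions

        starts = [d.start for d in enumerate_divisions(scheme)]
        for _ in range(reps):
            n_A = int(rng.choice(starts)) - 1
            series = make_ab_series(rng.normal(size=12), n_A)
            res = randomization_distribution(series, scheme, spec)
            counts[res.rank - 1] += 1
        expected = reps / m
        se = math.sqrt(reps * (1 / m) * (1 - 1 / m))
        assert np.all(np.abs(counts - expected) < 3.5 * se)
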