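"""Construct-validity battery: index agreement, associations, tertiles,
the lowest-tertile logistic model and the collinearity screen."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dqscore.errors import (
    AlignmentError,
    ConfigurationError,
    InsufficientDataError,
    ValidationError,
)
from dqscore.validity import (
    PredictorSpec,
    assign_tertiles,
    bivariate_association,
    collinearity_screen,
    compare_indices,
    fit_lowest_tertile_model,
    lowest_in_both,
    nagelkerke_r2,
)


class TestCompareIndices:
    def test_identical_vectors(self):
        r = compare_indices([50, 60, 70, 40], [50, 60, 70, 40])
        assert r.mean_difference == 0.0
        assert r.spearman_rho == pytest.approx(1.0)
        assert r.p_value == 1.0

    def test_constant_offset(self):
        a = [50.0, 60.0, 70.0, 40.0]
        b = [v + 5 for v in a]
        r = compare_indices(a, b)
        assert r.mean_difference == pytest.approx(-5.0)
        assert r.spearman_rho == pytest.approx(1.0)

    def test_spearman_matches_rank_formula_no_ties(self):
        """Oracle: 1 - 6*sum(d^2)/(n(n^2-1)) on hand-ranked 6-pair data."""
        a = [10.0, 25.0, 17.0, 32.0, 8.0, 41.0]
        b = [30.0, 41.0, 28.0, 35.0, 27.0, 50.0]
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        d2 = sum((x - y) ** 2 for x, y in zip(ra, rb))
        n = len(a)
        expected = 1 - 6 * d2 / (n * (n**2 - 1))
        r = compare_indices(a, b)
        assert r.spearman_rho == pytest.approx(expected)

    def test_antisymmetric_mean_difference(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(50, 9, 30), rng.normal(52, 9, 30)
        assert compare_indices(a, b).mean_difference == pytest.approx(
            -compare_indices(b, a).mean_difference)

    def test_unpaired_input_rejected(self):
        with pytest.raises(AlignmentError):
            compare_indices([1, 2, 3], [1, 2])


class TestBivariate:
    def test_perfect_monotone_rho_one(self):
        r = bivariate_association([1, 2, 3, 4], [10, 20, 30, 40], "continuous")
        assert r.statistic == pytest.approx(1.0)

    def test_identical_groups_t_zero(self):
        # both groups hold the values {5, 6}
        r = bivariate_association([5, 6, 5, 6], ["a", "a", "b", "b"], "binary")
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_anova_matches_sums_of_squares_oracle(self):
        scores = [1.0, 2.0, 3.0, 5.0, 6.0, 7.0, 10.0, 11.0, 12.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        grand = np.mean(scores)
        g_means = {g: np.mean([s for s, gg in zip(scores, groups) if gg == g])
                   for g in "abc"}
        ss_between = sum(3 * (g_means[g] - grand) ** 2 for g in "abc")
        ss_within = sum((s - g_means[g]) ** 2 for s, g in zip(scores, groups))
        f_expected = (ss_between / 2) / (ss_within / 6)
        r = bivariate_association(scores, groups, "multi")
        assert r.statistic == pytest.approx(f_expected)

    def test_spearman_equals_rank_then_pearson(self):
        """Oracle equivalence on 1000 random vectors (ties included)."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(4, 25))
            x = rng.integers(0, 8, n).astype(float)  # ties likely
            y = rng.normal(size=n)
            rho = bivariate_association(y, x, "continuous").statistic
            expected = np.corrcoef(stats.rankdata(y), stats.rankdata(x))[0, 1]
            if math.isnan(expected):
                assert math.isnan(rho)
            else:
                assert rho == pytest.approx(expected, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            bivariate_association([1, 2, 3], ["a", "a", "b"], "binary")


class TestTertiles:
    def test_scores_one_to_nine(self):
        scores = pd.Series({f"p{i}": float(i) for i in range(1, 10)})
        t = {a.participant_id: a.tertile for a in assign_tertiles(scores)}
        assert {p for p, v in t.items() if v == 1} == {"p1", "p2", "p3"}
        assert {p for p, v in t.items() if v == 2} == {"p4", "p5", "p6"}
        assert {p for p, v in t.items() if v == 3} == {"p7", "p8", "p9"}

    def test_260_distinct_scores_split_86_87_87(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.permutation(260).astype(float),
                           index=[f"p{i:03d}" for i in range(260)])
        t = assign_tertiles(scores)
        counts = pd.Series([a.tertile for a in t]).value_counts().sort_index()
        assert counts.tolist() == [86, 87, 87]

    def test_boundary_ties_share_a_tertile(self):
        # ranks: tie group at the T1/T2 boundary gets one average rank
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 3.0,
                            "e": 4.0, "f": 5.0})
        t = {a.participant_id: a.tertile for a in assign_tertiles(scores)}
        assert t["c"] == t["d"]

    def test_distinct_scores_partition_with_near_equal_sizes(self):
        rng = np.random.default_rng(3)
        for n in (9, 50, 101, 260):
            scores = pd.Series(rng.permutation(n).astype(float),
                               index=[f"p{i}" for i in range(n)])
            t = [a.tertile for a in assign_tertiles(scores)]
            counts = pd.Series(t).value_counts()
            assert sorted(counts.index) == [1, 2, 3]
            assert counts.sum() == n
            assert counts.max() - counts.min() <= 1

    def test_degenerate_distribution_warns_and_assigns_tertile_1(self):
        scores = pd.Series({"a": 5.0, "b": 5.0, "c": 5.0})
        with pytest.warns(UserWarning, match="degenerate"):
            t = assign_tertiles(scores)
        assert all(a.tertile == 1 for a in t)


class TestLowestInBoth:
    def _assign(self, mapping):
        scores = pd.Series(mapping)
        return assign_tertiles(scores)

    def test_joint_membership(self):
        a = self._assign({"p1": 1.0, "p2": 2.0, "p3": 3.0, "p4": 4.0, "p5": 5.0, "p6": 6.0})
        b = self._assign({"p1": 1.0, "p2": 6.0, "p3": 3.0, "p4": 4.0, "p5": 5.0, "p6": 2.0})
        out = lowest_in_both(a, b)
        assert out["p1"] == 1  # lowest in both
        assert out["p2"] == 0  # lowest in a only
        assert out.sum() <= min(
            sum(t.tertile == 1 for t in a), sum(t.tertile == 1 for t in b))

    def test_mismatched_sets_rejected(self):
        a = self._assign({"p1": 1.0, "p2": 2.0, "p3": 3.0})
        b = self._assign({"q1": 1.0, "q2": 2.0, "q3": 3.0})
        with pytest.raises(AlignmentError):
            lowest_in_both(a, b)


class TestLogisticModel:
    def test_null_model_nagelkerke_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 200) == 0.0

    def test_two_by_two_odds_ratio_equals_cross_product(self):
        # exposed: 30 events / 10 non-events; unexposed: 20 / 40
        y = pd.Series([1] * 30 + [0] * 10 + [1] * 20 + [0] * 40)
        prof = pd.DataFrame({"exposed": ["yes"] * 40 + ["no"] * 60})
        m = fit_lowest_tertile_model(
            y, prof,
            [PredictorSpec("exposed", "categorical", levels=("no", "yes"),
                           reference="no")])
        assert m.terms[0].odds_ratio == pytest.approx((30 * 40) / (10 * 20), rel=1e-4)
        assert m.terms[0].ci_low <= m.terms[0].odds_ratio <= m.terms[0].ci_high

    def test_parameter_recovery_on_simulated_logistic_data(self):
        """Data from a known logistic model (n=2000, beta=(-1, 0.8)): the
        fitted coefficient is within 0.15, and over 20 replicates the mean
        bias per coefficient is below 0.05."""
        rng = np.random.default_rng(12)
        biases = []
        for rep in range(20):
            x = rng.normal(size=2000)
            p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
            y = pd.Series(rng.binomial(1, p))
            m = fit_lowest_tertile_model(
                y, pd.DataFrame({"x": x}), [PredictorSpec("x", "continuous")])
            biases.append((m.coefficients["const"] + 1.0,
                           m.coefficients["x"] - 0.8))
            if rep == 0:
                assert abs(m.coefficients["x"] - 0.8) < 0.15
                assert abs(m.coefficients["const"] + 1.0) < 0.15
        mean_bias = np.abs(np.mean(biases, axis=0))
        assert (mean_bias < 0.05).all()

    def test_nagelkerke_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-x))))
        m1 = fit_lowest_tertile_model(
            y, pd.DataFrame({"x": x}), [PredictorSpec("x", "continuous")])
        m2 = fit_lowest_tertile_model(
            y, pd.DataFrame({"x": x * 1000}), [PredictorSpec("x", "continuous")])
        assert m1.nagelkerke_r2 == pytest.approx(m2.nagelkerke_r2, abs=1e-8)

    def test_single_class_outcome_rejected(self):
        y = pd.Series([1, 1, 1, 1])
        with pytest.raises(ValidationError):
            fit_lowest_tertile_model(
                y, pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}),
                [PredictorSpec("x", "continuous")])

    def test_classification_rate_in_unit_interval(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=300)
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-0.5 * x))))
        m = fit_lowest_tertile_model(
            y, pd.DataFrame({"x": x}), [PredictorSpec("x", "continuous")])
        assert 0.0 <= m.classification_rate <= 1.0
        assert 0.0 <= m.nagelkerke_r2 <= 1.0


class TestCollinearity:
    def test_weight_bmi_pair_drops_one(self):
        rng = np.random.default_rng(2)
        w = rng.normal(95, 14, 200)
        bmi = w / 2.6 + rng.normal(0, 1.0, 200)  # r ~ 0.95
        age = rng.uniform(18, 65, 200)
        prof = pd.DataFrame({"weight": w, "bmi": bmi, "age": age})
        report = collinearity_screen(prof, ["weight", "bmi", "age"])
        assert report.retained == ("weight", "age")
        assert len(report.dropped) == 1
        dropped, kept, r = report.dropped[0]
        assert (dropped, kept) == ("bmi", "weight") and r > 0.8

    def test_orthogonal_predictors_all_retained(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        report = collinearity_screen(prof, ["a", "b", "c"])
        assert report.retained == ("a", "b", "c")
        assert report.dropped == ()

    def test_priority_selects_representative_among_correlated_lipids(self):
        rng = np.random.default_rng(6)
        chol = rng.normal(5.3, 1.0, 200)
        ldl = 0.7 * chol + rng.normal(0, 0.1, 200)
        nonhdl = 0.9 * chol + rng.normal(0, 0.1, 200)
        prof = pd.DataFrame({"ldl": ldl, "cholesterol": chol, "non_hdl": nonhdl})
        report = collinearity_screen(
            prof, ["ldl", "cholesterol", "non_hdl"],
            priority=["cholesterol", "ldl", "non_hdl"])
        assert report.retained == ("cholesterol",)
        assert {d for d, _, _ in report.dropped} == {"ldl", "non_hdl"}

    def test_needs_two_predictors(self):
        with pytest.raises(ConfigurationError):
            collinearity_screen(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])
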