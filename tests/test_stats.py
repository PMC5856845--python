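import math

import numpy as np
import pytest
from scipy import stats as sps

from ccmorph.stats import (ancova_change, bootstrap_auc_test, compare_auc,
                           fit_quadratic, hanley_mcneil_se, mdc,
                           normalize_variable, paired_auc_test,
                           passing_bablok, roc_analysis, sem_from_sd,
                           summarize_groups)


def brute_force_auc(values, labels, direction="lower"):
    """Pairwise concordance enumeration (ties count ½)."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    cases, controls = v[y], v[~y]
    total = 0.0
    for c in cases:
        for k in controls:
            if (c < k) if direction == "lower" else (c > k):
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def brute_force_pb_slope(x, y):
    """Shifted median over all pairwise slopes, −1 excluded, offset K."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    S = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            if x[j] != x[i]:
                s = (y[j] - y[i]) / (x[j] - x[i])
                if s != -1.0:
                    S.append(s)
    S = np.sort(S)
    N = len(S)
    K = int((S < -1).sum())
    if N % 2:
        return S[(N + 1) // 2 - 1 + K]
    return 0.5 * (S[N // 2 - 1 + K] + S[min(N // 2 + K, N - 1)])


class TestRocAnalysis:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], "lower")
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_four_point_fixture(self):
        # cases {1, 3}, controls {2, 4}; concordant pairs 1<2, 1<4, 3<4
        r = roc_analysis([1, 2, 3, 4], [1, 0, 1, 0], "lower")
        assert r.auc == pytest.approx(3 / 4)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(6, 50))
            v = rng.integers(0, 20, size=n).astype(float)  # many ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            r = roc_analysis(v, y, "lower")
            assert r.auc == pytest.approx(brute_force_auc(v, y), abs=1e-12)

    def test_trapezoid_area_of_curve_equals_auc(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=40)
        y = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        v[y] -= 1.0
        r = roc_analysis(v, y, "lower")
        area = np.trapezoid(r.curve[:, 1], r.curve[:, 0])
        assert area == pytest.approx(r.auc, abs=1e-12)

    def test_cutpoint_maximizes_accuracy(self):
        v = np.array([1, 2, 3, 4, 5, 6], float)
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        r = roc_analysis(v, y, "lower")
        assert r.cutpoint == 3.0

    def test_direction_higher(self):
        r = roc_analysis([10, 11, 1, 2], [1, 1, 0, 0], "higher")
        assert r.auc == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_hanley_mcneil_se_closed_form(self):
        # hand evaluation of the Q1/Q2 formula at A = 0.8, 50/50
        a, m, n = 0.8, 50, 50
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (m - 1) * (q1 - a * a)
               + (n - 1) * (q2 - a * a)) / (m * n)
        assert hanley_mcneil_se(a, m, n) == pytest.approx(math.sqrt(var))


class TestCompareAuc:
    def test_identical_scores_give_zero_z(self):
        v = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        z, p, *_ = paired_auc_test(v, v, y)
        assert z == 0.0 and p == 1.0

    def test_unpaired_reduces_to_independent_z(self):
        r1 = roc_analysis([1, 2, 3, 9, 10, 11], [1, 1, 1, 0, 0, 0])
        r2 = roc_analysis([1, 9, 3, 2, 10, 11], [1, 1, 1, 0, 0, 0])
        z, p = compare_auc(r1, r2, paired=False)
        zhand = (r1.auc - r2.auc) / math.sqrt(r1.se_auc**2 + r2.se_auc**2)
        assert z == pytest.approx(zhand)
        assert p == pytest.approx(2 * sps.norm.sf(abs(zhand)))

    def test_swapping_inputs_negates_z(self):
        rng = np.random.default_rng(5)
        y = np.concatenate([np.ones(15, bool), np.zeros(15, bool)])
        v1 = rng.normal(size=30) - y
        v2 = 0.7 * v1 + rng.normal(size=30)
        z1, _, r1, r2 = paired_auc_test(v1, v2, y)
        z2, _, _, _ = paired_auc_test(v2, v1, y)
        assert z2 == pytest.approx(-z1)

    def test_paired_needs_correlation(self):
        r1 = roc_analysis([1, 2, 3, 4], [1, 0, 1, 0])
        with pytest.raises(ValueError):
            compare_auc(r1, r1, paired=True)


class TestPassingBablok:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.5, 8.0, 9.0, 11.0, 13.0])
        fit = passing_bablok(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_five_point_fixture_matches_brute_force(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([1.5, 2.2, 4.9, 5.1, 8.4])
        fit = passing_bablok(x, y)
        assert fit.slope == pytest.approx(brute_force_pb_slope(x, y))

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 25))
            x = rng.normal(10, 3, size=n)
            y = 1.3 * x + rng.normal(0, 1, size=n)
            fit = passing_bablok(x, y)
            assert fit.slope == pytest.approx(brute_force_pb_slope(x, y))

    def test_affine_equivariance(self):
        # positive-slope fixture: no pairwise slope can cross the -1
        # shift point, where equivariance would break
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.uniform(1, 2, size=15))
        y = 0.9 * x + rng.uniform(-0.2, 0.2, size=15)
        f0 = passing_bablok(x, y)
        f1 = passing_bablok(x, 2 * y + 3)
        assert f1.slope == pytest.approx(2 * f0.slope)
        assert f1.intercept == pytest.approx(2 * f0.intercept + 3)

    def test_axis_swap_gives_reciprocal_slope(self):
        rng = np.random.default_rng(11)
        x = rng.normal(20, 4, size=21)
        y = 1.7 * x + rng.normal(0, 0.8, size=21)
        fwd = passing_bablok(x, y)
        rev = passing_bablok(y, x)
        assert rev.slope == pytest.approx(1.0 / fwd.slope, rel=0.05)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(13)
        x = rng.normal(10, 3, size=30)
        y = 1.1 * x + rng.normal(0, 1, size=30)
        fit = passing_bablok(x, y)
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            passing_bablok([2, 2, 2, 2], [1, 2, 3, 4])


class TestFitQuadratic:
    # published NFL↔NFA pixel-unit relation used as a noiseless generator
    A, B, C = 2.78e-4, 0.72, 471.0

    def test_noiseless_recovery_to_1e9(self):
        x = np.linspace(200, 4000, 25)
        y = self.A * x**2 + self.B * x + self.C
        fit = fit_quadratic(x, y)
        assert fit.a == pytest.approx(self.A, abs=1e-9)
        assert fit.b == pytest.approx(self.B, abs=1e-9)
        assert fit.c == pytest.approx(self.C, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_linear_data_gives_negligible_curvature(self):
        rng = np.random.default_rng(15)
        x = np.linspace(0, 10, 40)
        y = 2 * x + 1 + rng.normal(0, 1e-9, size=40)
        fit = fit_quadratic(x, y)
        assert abs(fit.a) < 1e-9

    def test_predict_and_out_of_sample_r2(self):
        x = np.linspace(200, 4000, 30)
        y = self.A * x**2 + self.B * x + self.C
        fit = fit_quadratic(x, y)
        assert fit.r2_on(x, y) == pytest.approx(1.0)

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            fit_quadratic([3, 3, 3, 3], [1, 2, 3, 4])


class TestMdc:
    def test_zero(self):
        assert mdc(0.0) == 0.0

    def test_unit_sem_closed_form(self):
        assert mdc(1.0) == pytest.approx(2.771859, abs=1e-6)

    def test_linearity(self):
        for k in (0.5, 2.0, 7.3):
            assert mdc(k * 0.37) == pytest.approx(k * mdc(0.37), rel=1e-12)

    def test_sarcoidosis_nfl_consistency(self):
        """sd 2.9 over n = 63 gives SEM 0.365 and MDC ≈ 1.01, matching the
        published 1.03 to the rounding of the reported sd."""
        sem = sem_from_sd(2.9, n=63)
        assert mdc(sem) == pytest.approx(1.013, abs=0.002)
        assert mdc(sem) == pytest.approx(1.03, abs=0.05)

    def test_negative_sem_raises(self):
        with pytest.raises(ValueError):
            mdc(-0.1)

    def test_sem_variants(self):
        assert sem_from_sd(3.0, n=9) == pytest.approx(1.0)
        assert sem_from_sd(2.0, icc=0.75) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sem_from_sd(1.0)


class TestNormalizeVariable:
    def test_square_root_values(self):
        out = normalize_variable([0.0, 1.0, 4.0, 9.0])
        assert np.allclose(out["transformed"], [0, 1, 2, 3])

    def test_all_equal_flagged(self):
        out = normalize_variable([2.0] * 10)
        assert out["w_pre"] is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_variable([-1.0, 4.0])

    def test_shapiro_matches_r_reference(self):
        """scipy's Shapiro–Wilk agrees with R's shapiro.test to 1e-6 on
        frozen fixtures."""
        x1 = [2.1, 3.5, 1.2, 4.8, 2.9, 3.3, 5.1, 2.2, 4.4, 3.0, 1.9, 3.7]
        x2 = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 20.0]
        w1, p1 = sps.shapiro(x1)
        w2, p2 = sps.shapiro(x2)
        assert w1 == pytest.approx(0.9721550129, abs=1e-6)
        assert p1 == pytest.approx(0.9320155362, abs=1e-6)
        assert w2 == pytest.approx(0.5885885076, abs=1e-6)
        assert p2 == pytest.approx(0.0000404447, abs=1e-6)

    def test_sqrt_improves_normality_of_squared_gaussians(self):
        """Area-like data (squares of Gaussians, strongly right-skewed at
        low mean/sd ratio) become more normal under the square root in
        ≥ 95% of replicates."""
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(200):
            v = rng.normal(2, 1, size=40) ** 2
            out = normalize_variable(v)
            wins += out["w_post"] > out["w_pre"]
        assert wins >= 190


class TestAncovaChange:
    def test_no_change_gives_zero_effect(self):
        rng = np.random.default_rng(19)
        b = rng.normal(10, 2, size=20)
        arm = np.array(["placebo"] * 10 + ["treatment"] * 10)
        res = ancova_change(b, b, arm)
        assert res.effect == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_on_fixture(self):
        b = np.array([10, 12, 9, 11, 13, 10, 12, 14, 9, 11], float)
        f = np.array([11, 12, 10, 12, 14, 12, 14, 15, 11, 13], float)
        arm = np.array(["p"] * 5 + ["t"] * 5)
        X = np.column_stack([np.ones(10), b, (arm == "t").astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ f)
        res = ancova_change(b, f, arm)
        assert res.effect == pytest.approx(beta[2], rel=1e-10)
        assert res.baseline_coef == pytest.approx(beta[1], rel=1e-10)

    def test_single_arm_raises(self):
        with pytest.raises(ValueError):
            ancova_change([1, 2, 3], [1, 2, 3], ["a", "a", "a"])


class TestSummarizeGroups:
    import pandas as pd

    def _table(self):
        import pandas as pd
        return pd.DataFrame({
            "group": ["control"] * 4 + ["case"] * 4,
            "nfl": [16.0, 18.0, 17.0, 17.0, 8.0, 10.0, 9.0, 9.0],
            "nfd": [28.0, 30.0, 29.0, 29.0, 14.0, 15.0, 16.0, 15.0],
        })

    def test_hand_computed_summaries(self):
        gs = summarize_groups(self._table(), "control")
        s = gs.stats["case"]["nfl"]
        assert s.mean == pytest.approx(9.0)
        assert s.sd == pytest.approx(np.std([8, 10, 9, 9], ddof=1))
        assert s.sem == pytest.approx(s.sd / 2)
        assert s.percent_of_control == pytest.approx(100 * 9.0 / 17.0)

    def test_control_percent_is_100(self):
        gs = summarize_groups(self._table(), "control")
        assert gs.stats["control"]["nfl"].percent_of_control == pytest.approx(100.0)

    def test_collinear_variables_have_unit_correlation(self):
        import pandas as pd
        df = pd.DataFrame({"group": ["g"] * 6 + ["control"] * 6,
                           "a": np.arange(12.0)})
        df["b"] = 2 * df["a"] + 1
        gs = summarize_groups(df, "control")
        assert gs.correlations["g"].loc["a", "b"] == pytest.approx(1.0)

    def test_tukey_flags_separated_groups(self):
        gs = summarize_groups(self._table(), "control")
        rows = gs.tukey["nfl"]
        assert bool(rows.iloc[0]["reject"])

    def test_missing_control_raises(self):
        import pandas as pd
        df = pd.DataFrame({"group": ["a", "b"], "nfl": [1.0, 2.0]})
        with pytest.raises(ValueError):
            summarize_groups(df, "control")


class TestBootstrapCrossCheck:
    def test_bootstrap_agrees_with_hm_on_one_dataset(self):
        rng = np.random.default_rng(23)
        n = 30
        y = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        base = rng.normal(size=2 * n) - 1.2 * y
        v1 = base + rng.normal(0, 0.6, size=2 * n)
        v2 = base + rng.normal(0, 0.6, size=2 * n)
        z_hm, p_hm, *_ = paired_auc_test(v1, v2, y)
        z_bs, p_bs = bootstrap_auc_test(v1, v2, y, n_boot=800, seed=1)
        assert p_hm == pytest.approx(p_bs, abs=0.1)
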