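"""Curve fitting, cross-validated selection, permutation inference, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import devconn as dc
from devconn.trajectories import MODEL_KINDS, TrajectoryModel


@pytest.fixture(scope="module")
def ages():
    return np.random.default_rng(3).uniform(6, 45, 120)


class TestFitModel:
    def test_linear_exact_recovery(self, ages):
        model = dc.fit_model("linear", ages, 2 * ages + 1)
        assert model.coefficients == pytest.approx((2.0, 1.0), abs=1e-8)

    def test_quadratic_exact_recovery(self, ages):
        model = dc.fit_model("quadratic", ages, ages**2 - 3 * ages + 5)
        assert model.coefficients == pytest.approx((1.0, -3.0, 5.0), abs=1e-8)

    def test_logarithmic_curve_recovery(self, ages):
        # the 4-coefficient log family is over-parameterised, so assert
        # recovery of the curve values rather than the coefficient vector
        y = 3 * np.log10(ages + 1) + 0.5
        model = dc.fit_model("logarithmic", ages, y)
        rms = np.sqrt(np.mean((dc.predict(model, ages) - y) ** 2))
        assert rms < 1e-4

    def test_log_argument_positive_over_data(self, ages):
        y = np.log10(ages - 5.0)  # bends hard near the youngest age
        model = dc.fit_model("logarithmic", ages, y)
        c1, c2, c3, c4 = model.coefficients
        assert c2 * ages.min() + c3 > 0

    def test_insufficient_distinct_x_raises(self):
        with pytest.raises(ValueError):
            dc.fit_model("quadratic", [1.0, 1.0, 2.0, 2.0], [0.0, 0.0, 1.0, 1.0])

    def test_unknown_kind_raises(self, ages):
        with pytest.raises(ValueError):
            dc.fit_model("cubic", ages, ages)


class TestPredict:
    @pytest.mark.parametrize(
        "kind,coeffs,x,expected",
        [
            ("linear", (2.0, 1.0), 3.0, 7.0),
            ("quadratic", (1.0, 0.0, 0.0), 4.0, 16.0),
            ("logarithmic", (1.0, 1.0, 0.0, 0.0), 100.0, 2.0),
        ],
    )
    def test_formula_evaluation(self, kind, coeffs, x, expected):
        model = TrajectoryModel(kind=kind, coefficients=coeffs)
        assert dc.predict(model, np.array([x]))[0] == pytest.approx(expected)

    def test_log_nonpositive_argument_raises(self):
        model = TrajectoryModel(kind="logarithmic", coefficients=(1.0, 1.0, -10.0, 0.0))
        with pytest.raises(ValueError):
            dc.predict(model, np.array([5.0]))


class TestCvSelectModel:
    def test_noise_free_quadratic_selected(self, ages):
        y = -0.01 * ages**2 + 0.5 * ages + 1
        sel = dc.cv_select_model(ages, y, n_iterations=50, seed=0)
        assert sel.selected_kind == "quadratic"

    def test_noise_free_linear_wins_tie_break(self, ages):
        # quadratic (b1=0) also fits exactly; parsimony must break the tie
        sel = dc.cv_select_model(ages, 0.3 * ages + 2, n_iterations=50, seed=0)
        assert sel.selected_kind == "linear"

    def test_selected_kind_attains_minimum_median(self, ages, rng):
        y = 0.3 * ages + rng.normal(0, 1, ages.size)
        sel = dc.cv_select_model(ages, y, n_iterations=100, seed=1)
        best = min(sel.median_residuals.values())
        assert sel.median_residuals[sel.selected_kind] == pytest.approx(best, rel=1e-9)

    def test_subject_order_invariance(self, ages, rng):
        y = 0.3 * ages + rng.normal(0, 1, ages.size)
        sel1 = dc.cv_select_model(ages, y, n_iterations=40, seed=5)
        perm = rng.permutation(ages.size)
        sel2 = dc.cv_select_model(ages[perm], y[perm], n_iterations=40, seed=5)
        assert sel1.selected_kind == sel2.selected_kind
        assert sel1.median_residuals == sel2.median_residuals

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError):
            dc.cv_select_model([1, 2, 3, 4], [1, 2, 3, 4], n_iterations=5, seed=0)


class TestFStatistic:
    def test_matches_hand_solved_normal_equations(self):
        # 10-point dataset solved independently: for y = a x + b by normal
        # equations, F = ((TSS-RSS)/1)/(RSS/(n-2))
        x = np.arange(10, dtype=float)
        y = np.array([1.1, 2.3, 2.8, 4.5, 4.9, 6.2, 6.8, 8.5, 9.1, 9.8])
        n = len(x)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        a = sxy / sxx
        b = y.mean() - a * x.mean()
        rss = ((y - (a * x + b)) ** 2).sum()
        tss = ((y - y.mean()) ** 2).sum()
        f_oracle = ((tss - rss) / 1) / (rss / (n - 2))
        model = dc.fit_model("linear", x, y)
        assert dc.f_statistic(model, x, y) == pytest.approx(f_oracle, rel=1e-10)

    def test_constant_y_is_nan(self):
        x = np.arange(10, dtype=float)
        model = TrajectoryModel(kind="linear", coefficients=(0.0, 5.0))
        assert np.isnan(dc.f_statistic(model, x, np.full(10, 5.0)))

    def test_perfect_fit_is_infinite(self):
        x = np.arange(10, dtype=float)
        model = dc.fit_model("linear", x, 2 * x + 1)
        assert np.isinf(dc.f_statistic(model, x, 2 * x + 1))


class TestPermutationPvalue:
    def test_strong_signal_p_zero(self, rng):
        x = rng.uniform(6, 45, 300)
        y = 0.5 * x + rng.normal(0, 1, 300)
        inf = dc.permutation_pvalue("linear", x, y, n_permutations=1000, seed=0)
        assert inf.p_perm == 0.0

    def test_null_p_moderate(self, rng):
        x = rng.uniform(6, 45, 60)
        y = rng.normal(0, 1, 60)
        inf = dc.permutation_pvalue("linear", x, y, n_permutations=500, seed=0)
        assert 0.01 < inf.p_perm <= 1.0

    def test_polynomial_null_matches_direct_refit(self, rng):
        """The multi-RHS shortcut must equal literally refitting on shuffled ages."""
        x = rng.uniform(6, 45, 40)
        y = 0.1 * x + rng.normal(0, 0.5, 40)
        n_perm = 200
        inf = dc.permutation_pvalue("quadratic", x, y, n_permutations=n_perm, seed=9)
        # direct route: shuffle ages, refit, count
        rng2 = np.random.default_rng(9)
        idx = np.argsort(rng2.random((n_perm, len(x))), axis=1)
        count = 0
        for p in range(n_perm):
            y_p = y[idx[p]]
            m = dc.fit_model("quadratic", x, y_p)
            if dc.f_statistic(m, x, y_p) >= inf.F_obs:
                count += 1
        assert inf.p_perm == pytest.approx(count / n_perm, abs=1e-12)

    def test_log_kind_null(self, rng):
        x = rng.uniform(6, 45, 50)
        y = np.log10(x - 5) + rng.normal(0, 0.2, 50)
        inf = dc.permutation_pvalue("logarithmic", x, y, n_permutations=200, seed=1)
        assert inf.p_perm <= 0.05

    def test_deterministic_under_seed(self, rng):
        x = rng.uniform(6, 45, 40)
        y = rng.normal(0, 1, 40)
        a = dc.permutation_pvalue("linear", x, y, n_permutations=300, seed=3)
        b = dc.permutation_pvalue("linear", x, y, n_permutations=300, seed=3)
        assert a.p_perm == b.p_perm and a.F_obs == b.F_obs


def _bh_bruteforce(p, q):
    """Try every rejection set defined by the sorted p-values (step-up)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            k_star = i
    mask = np.zeros(m, bool)
    mask[order[:k_star]] = True
    return mask


class TestBhFdr:
    def test_hand_step_up(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.2]
        assert dc.bh_fdr(p, q=0.05).tolist() == [True, True, True, True, False]

    @pytest.mark.parametrize("p,expected", [([0.0] * 4, True), ([0.9] * 4, False)])
    def test_degenerate_vectors(self, p, expected):
        assert np.all(dc.bh_fdr(p, q=0.05) == expected)

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.random(m)
            assert np.array_equal(dc.bh_fdr(p, 0.05), _bh_bruteforce(p, 0.05))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dc.bh_fdr([])


class TestCurveGradient:
    def test_linear_constant_gradient(self):
        model = TrajectoryModel(kind="linear", coefficients=(0.7, 1.0))
        grid = np.arange(6, 46)
        assert np.all(dc.curve_gradient(model, grid) == 0.7)

    def test_quadratic_substitution(self):
        model = TrajectoryModel(kind="quadratic", coefficients=(1.0, -2.0, 0.0))
        assert dc.curve_gradient(model, np.array([3.0]))[0] == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "kind,coeffs",
        [
            ("linear", (0.7, 2.0)),
            ("quadratic", (-0.01, 0.6, 1.0)),
            ("logarithmic", (1.0, 1.0, 0.0, 0.0)),
            ("logarithmic", (2.5, 0.8, 3.0, -1.0)),
        ],
    )
    def test_matches_finite_differences(self, kind, coeffs):
        model = TrajectoryModel(kind=kind, coefficients=coeffs)
        grid = np.linspace(6, 45, 40)
        h = 1e-6
        fd = (dc.predict(model, grid + h) - dc.predict(model, grid - h)) / (2 * h)
        assert dc.curve_gradient(model, grid) == pytest.approx(fd, abs=1e-6)


class TestModelSd:
    def test_flat_model_zero(self):
        model = TrajectoryModel(kind="linear", coefficients=(0.0, 3.0))
        assert dc.model_sd(model, np.arange(6, 46)) == 0.0

    def test_unit_slope_equals_grid_sd(self):
        model = TrajectoryModel(kind="linear", coefficients=(1.0, 0.0))
        grid = np.arange(6, 46, dtype=float)
        assert dc.model_sd(model, grid) == pytest.approx(np.std(grid))

    def test_intercept_invariance(self):
        grid = np.arange(6, 46, dtype=float)
        a = TrajectoryModel(kind="quadratic", coefficients=(0.1, -1.0, 0.0))
        b = TrajectoryModel(kind="quadratic", coefficients=(0.1, -1.0, 42.0))
        assert dc.model_sd(a, grid) == pytest.approx(dc.model_sd(b, grid))


class TestSexSubsampleStability:
    def test_frequencies_partition(self, rng):
        x = rng.uniform(6, 45, 60)
        y = 0.3 * x + rng.normal(0, 2, 60)
        sex = np.array(["female"] * 20 + ["male"] * 40)
        freq = dc.sex_subsample_stability(
            x, y, sex, n_repeats=5, seed=0, n_cv_iterations=30
        )
        assert sum(freq.values()) == pytest.approx(1.0)

    def test_strong_linear_signal_stable(self, rng):
        x = rng.uniform(6, 45, 80)
        y = 0.5 * x + rng.normal(0, 1.0, 80)
        sex = np.array(["female"] * 40 + ["male"] * 40)
        freq = dc.sex_subsample_stability(
            x, y, sex, n_repeats=20, seed=1, n_cv_iterations=50
        )
        assert freq["linear"] > 0.5

    def test_single_sex_raises(self, rng):
        x = rng.uniform(6, 45, 30)
        with pytest.raises(ValueError):
            dc.sex_subsample_stability(x, x, np.array(["male"] * 30), n_repeats=2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_gradient_finite_difference_property(seed):
    """Analytic gradients agree with central differences for random coefficients."""
    rng = np.random.default_rng(seed)
    kind = MODEL_KINDS[seed % 3]
    if kind == "linear":
        coeffs = tuple(rng.normal(0, 2, 2))
    elif kind == "quadratic":
        coeffs = tuple(rng.normal(0, 1, 3))
    else:
        coeffs = (rng.normal(0, 2), rng.uniform(0.2, 3), rng.uniform(1, 10), rng.normal())
    model = TrajectoryModel(kind=kind, coefficients=coeffs)
    grid = np.linspace(6, 45, 20)
    h = 1e-6
    fd = (dc.predict(model, grid + h) - dc.predict(model, grid - h)) / (2 * h)
    assert dc.curve_gradient(model, grid) == pytest.approx(fd, abs=1e-5)
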