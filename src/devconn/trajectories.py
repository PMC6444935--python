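"""Developmental trajectory fitting: model selection, inference, gradients.

Three parametric growth curves are fitted to a graph metric y against
age x:

    linear       y = a1*x + a2
    quadratic    y = b1*x**2 + b2*x + b3
    logarithmic  y = c1*log10(c2*x + c3) + c4

Model selection uses repeated split-half cross-validation: subjects are
randomly split into equal Fit and Test halves, all three models are
estimated on Fit and scored on Test by mean absolute deviation, and the
kind with the lowest *median* test residual across iterations wins
(median, not mean, so the selection is not biased toward flexible
models). Significance of the winning curve comes from a permutation
test: the regression F statistic of the full-data fit is compared with
the F distribution obtained by refitting after randomly shuffling ages.
Region-wise p-values are controlled with Benjamini-Hochberg FDR.

The logarithmic family is over-parameterised: c1*log10(c2*x + c3) + c4
equals c1*log10(x + c3/c2) + (c4 + c1*log10(c2)), so only the fitted
curve — not the individual coefficients — is identifiable.  The fit is
solved by variable projection over the single identifiable offset
r = c3/c2 (coarse grid plus bounded 1-D refinement; c1 and c4 solved
linearly at each r) and reported as (c1, 1, r, c4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

#: Model kinds in increasing order of coefficient count (tie-break order).
MODEL_KINDS = ("linear", "quadratic", "logarithmic")

_N_COEFFS = {"linear": 2, "quadratic": 3, "logarithmic": 4}

_LOG_ARG_FLOOR = 1e-6
LN10 = np.log(10.0)


@dataclass
class TrajectoryModel:
    """A fitted growth curve of one of the three kinds."""

    kind: str
    coefficients: tuple
    fit_valid: bool = True

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(self.coefficients) != _N_COEFFS[self.kind]:
            raise ValueError(
                f"{self.kind} model needs {_N_COEFFS[self.kind]} coefficients, "
                f"got {len(self.coefficients)}"
            )

    @property
    def n_coefficients(self) -> int:
        return _N_COEFFS[self.kind]


@dataclass
class CvSelectionResult:
    """Outcome of split-half cross-validated model selection."""

    median_residuals: dict
    selected_kind: str
    n_iterations: int
    seed: int


@dataclass
class FitInference:
    """Permutation inference and descriptive quantities for a selected fit."""

    model: TrajectoryModel
    F_obs: float
    p_perm: float
    n_permutations: int
    q_significant: bool = False
    gradient_track: np.ndarray | None = None
    model_sd: float = np.nan


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite data")
    return x, y


def _log_rss(r: float, x: np.ndarray, yc: np.ndarray, ssy: float):
    """RSS of y ~ A*log10(x+r) + B at fixed offset r (A, B solved linearly)."""
    u = np.log10(x + r)
    uc = u - u.mean()
    ssu = float(uc @ uc)
    if ssu <= 0:
        return ssy, 0.0, 0.0
    cross = float(uc @ yc)
    return ssy - cross * cross / ssu, cross / ssu, u.mean()


def _fit_logarithmic(
    x: np.ndarray, y: np.ndarray, domain_min: float | None = None
) -> tuple[tuple, float]:
    """Variable-projection fit of the logarithmic curve; returns (coeffs, rss)."""
    x_min = x.min()
    # the fitted curve must stay defined over the whole evaluation domain —
    # held-out subjects younger than the training minimum and the start of
    # the integer-year grid — not just over the training ages
    dmin = x_min if domain_min is None else min(domain_min, x_min)
    lo = -np.floor(dmin) + 0.01
    span = max(x.max() - x_min, 1.0)
    # coarse grid of candidate offsets, dense near the singular end where the
    # curve bends hardest, stretching to the near-linear regime at large r
    grid = lo + np.geomspace(1e-3 * span, 1e4 * span, 60)
    ym = y.mean()
    yc = y - ym
    ssy = float(yc @ yc)
    rss_grid = np.array([_log_rss(r, x, yc, ssy)[0] for r in grid])
    i_best = int(np.argmin(rss_grid))
    lo_b = grid[max(i_best - 1, 0)]
    hi_b = grid[min(i_best + 1, len(grid) - 1)]
    if hi_b > lo_b:
        res = minimize_scalar(
            lambda r: _log_rss(r, x, yc, ssy)[0],
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-10 * span},
        )
        r_best = float(res.x) if res.fun <= rss_grid[i_best] else float(grid[i_best])
    else:
        r_best = float(grid[i_best])
    rss, slope, u_mean = _log_rss(r_best, x, yc, ssy)
    c1 = slope
    c4 = ym - slope * u_mean
    return (c1, 1.0, r_best, c4), float(rss)


def fit_model(kind: str, x, y, domain_min: float | None = None) -> TrajectoryModel:
    """Least-squares fit of one model kind.

    Linear and quadratic fits are closed-form polynomial least squares;
    the logarithmic fit is a variable-projection nonlinear least squares
    honouring ``c2*x + c3 > 0`` down to ``domain_min`` (default: the data
    minimum), so the curve stays evaluable on held-out subjects younger
    than any training subject. A solver failure yields
    ``fit_valid=False`` rather than an exception.
    """
    x, y = _check_xy(x, y)
    k = _N_COEFFS.get(kind)
    if k is None:
        raise ValueError(f"unknown model kind {kind!r}")
    if len(np.unique(x)) < k:
        raise ValueError(f"{kind} fit needs >= {k} distinct x values")
    try:
        if kind == "linear":
            coeffs = tuple(np.polyfit(x, y, 1))
        elif kind == "quadratic":
            coeffs = tuple(np.polyfit(x, y, 2))
        else:
            coeffs, _ = _fit_logarithmic(x, y, domain_min=domain_min)
        model = TrajectoryModel(kind=kind, coefficients=coeffs)
        if not all(np.isfinite(c) for c in coeffs):
            model.fit_valid = False
        return model
    except (np.linalg.LinAlgError, ValueError):
        return TrajectoryModel(kind=kind, coefficients=(np.nan,) * k, fit_valid=False)


def predict(model: TrajectoryModel, x) -> np.ndarray:
    """Evaluate a fitted curve at ages ``x``."""
    if not model.fit_valid:
        raise ValueError("cannot predict from an invalid fit")
    x = np.asarray(x, dtype=float)
    c = model.coefficients
    if model.kind == "linear":
        return c[0] * x + c[1]
    if model.kind == "quadratic":
        return c[0] * x**2 + c[1] * x + c[2]
    arg = c[1] * x + c[2]
    if np.any(arg <= 0):
        raise ValueError("logarithmic argument c2*x + c3 <= 0 at requested x")
    return c[0] * np.log10(arg) + c[3]


def _canonical_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # splits are applied to indices after a canonical sort, so selection is
    # invariant to the order subjects arrive in
    return np.lexsort((y, x))


def cv_select_model(x, y, n_iterations: int = 1000, seed: int = 0) -> CvSelectionResult:
    """Split-half cross-validated selection among the three model kinds.

    Each iteration randomly splits subjects into equal Fit and Test groups
    (Fit receives the extra subject when n is odd), fits all three models
    on Fit, and scores each on Test by mean absolute deviation between
    predictions and observed values. The kind with the lowest median test
    residual across iterations is selected; near-exact ties go to the
    model with fewer coefficients. A failed fit contributes an infinite
    residual for that iteration and kind.
    """
    x, y = _check_xy(x, y)
    n = len(x)
    if n < 8:
        raise ValueError("need at least 8 subjects for split-half selection")
    order = _canonical_order(x, y)
    xs, ys = x[order], y[order]
    n_fit = (n + 1) // 2
    rng = np.random.default_rng(seed)
    residuals = {kind: np.empty(n_iterations) for kind in MODEL_KINDS}
    for it in range(n_iterations):
        perm = rng.permutation(n)
        fit_idx, test_idx = perm[:n_fit], perm[n_fit:]
        xf, yf = xs[fit_idx], ys[fit_idx]
        xt, yt = xs[test_idx], ys[test_idx]
        for kind in MODEL_KINDS:
            try:
                model = fit_model(kind, xf, yf, domain_min=float(xs[0]))
                if not model.fit_valid:
                    raise ValueError
                resid = float(np.mean(np.abs(predict(model, xt) - yt)))
            except ValueError:
                resid = np.inf
            residuals[kind][it] = resid
    medians = {kind: float(np.median(residuals[kind])) for kind in MODEL_KINDS}
    finite = [m for m in medians.values() if np.isfinite(m)]
    if not finite:
        raise ValueError("all model kinds failed in cross-validation")
    best = min(finite)
    tol = 1e-9 * (1.0 + abs(best) + float(np.std(y)))
    selected = next(k for k in MODEL_KINDS if medians[k] <= best + tol)
    return CvSelectionResult(
        median_residuals=medians,
        selected_kind=selected,
        n_iterations=n_iterations,
        seed=seed,
    )


def f_statistic(model: TrajectoryModel, x, y) -> float:
    """Regression F of the fitted curve against the intercept-only model.

    ``F = ((TSS - RSS)/(k - 1)) / (RSS/(n - k))`` with k the number of
    free coefficients. A perfect fit (RSS = 0) returns +inf (maximal
    evidence); a constant y (TSS = 0) returns NaN (undefined).
    """
    x, y = _check_xy(x, y)
    if not model.fit_valid:
        raise ValueError("invalid fit")
    k = model.n_coefficients
    n = len(x)
    if n <= k:
        raise ValueError(f"need n > {k} observations for the F statistic")
    resid = y - predict(model, x)
    rss = float(resid @ resid)
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        return np.nan
    if rss <= 1e-12 * tss:  # exact fit up to roundoff
        return np.inf
    return ((tss - rss) / (k - 1)) / (rss / (n - k))


def _null_f_polynomial(kind, x, y, n_permutations, rng) -> np.ndarray:
    """Null F values for shuffled-age polynomial fits, via multi-RHS lstsq.

    Shuffling the ages x by a permutation P while holding y fixed gives the
    same residual sum of squares as regressing the inversely shuffled y on
    the original design (permutation matrices are orthogonal), so all null
    fits reduce to one least-squares solve with many right-hand sides.
    """
    k = _N_COEFFS[kind]
    deg = k - 1
    X = np.vander(x, N=k)  # columns x^deg .. 1
    idx = np.argsort(rng.random((n_permutations, len(x))), axis=1)
    Y = y[idx].T  # each column: y under one (inverse) age shuffle
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    yc = y - y.mean()
    tss = float(yc @ yc)
    n = len(x)
    with np.errstate(divide="ignore"):
        return ((tss - rss) / (k - 1)) / np.maximum(rss / (n - k), 1e-300)


def permutation_pvalue(
    kind: str, x, y, n_permutations: int = 15000, seed: int = 0
) -> FitInference:
    """Permutation test of a model kind: shuffle ages, refit, compare F.

    The observed F comes from the unshuffled fit; each permutation refits
    the same kind with ages randomly shuffled against the metric values,
    and ``p = #{F_null >= F_obs} / n_permutations`` (upper tail, no
    smoothing, so p = 0 is reportable at 1/n resolution). Aborts if more
    than half the permutation refits fail.
    """
    x, y = _check_xy(x, y)
    model = fit_model(kind, x, y)
    if not model.fit_valid:
        raise ValueError(f"{kind} fit failed on the observed data")
    f_obs = f_statistic(model, x, y)
    if np.isnan(f_obs):
        raise ValueError("F statistic undefined (constant y)")
    rng = np.random.default_rng(seed)
    if kind in ("linear", "quadratic"):
        f_null = _null_f_polynomial(kind, x, y, n_permutations, rng)
    else:
        f_null = np.empty(n_permutations)
        n_failed = 0
        yc_all = y - y.mean()
        tss = float(yc_all @ yc_all)  # invariant under shuffling
        n, k = len(x), 4
        for p in range(n_permutations):
            y_p = y[rng.permutation(n)]
            try:
                _, rss = _fit_logarithmic(x, y_p)
                if rss <= 0:
                    f_null[p] = np.inf
                else:
                    f_null[p] = ((tss - rss) / (k - 1)) / (rss / (n - k))
            except (ValueError, np.linalg.LinAlgError):
                f_null[p] = np.nan
                n_failed += 1
        if n_failed > n_permutations / 2:
            raise ValueError(
                f"{n_failed}/{n_permutations} permutation refits failed; "
                "permutation null unusable"
            )
        f_null = f_null[~np.isnan(f_null)]
    # failed refits count against the numerator only (conservative)
    p_perm = float(np.sum(f_null >= f_obs)) / n_permutations
    return FitInference(
        model=model, F_obs=float(f_obs), p_perm=p_perm, n_permutations=n_permutations
    )


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def curve_gradient(model: TrajectoryModel, ages) -> np.ndarray:
    """Analytic per-year gradient of a fitted curve.

    linear: a1; quadratic: 2*b1*x + b2;
    logarithmic: c1*c2 / ((c2*x + c3) * ln 10).
    """
    if not model.fit_valid:
        raise ValueError("invalid fit")
    ages = np.asarray(ages, dtype=float)
    c = model.coefficients
    if model.kind == "linear":
        return np.full_like(ages, c[0])
    if model.kind == "quadratic":
        return 2.0 * c[0] * ages + c[1]
    arg = c[1] * ages + c[2]
    if np.any(arg <= 0):
        raise ValueError("logarithmic argument non-positive on the age grid")
    return c[0] * c[1] / (arg * LN10)


def model_sd(model: TrajectoryModel, ages) -> float:
    """Standard deviation of predicted values over an age grid.

    Summarises how much the metric changes across the developmental span
    (population SD over the integer-year grid spanning the cohort).
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValueError("age grid needs at least 2 points")
    return float(np.std(predict(model, ages)))


def sex_subsample_stability(
    x,
    y,
    sex,
    n_repeats: int = 100,
    seed: int = 0,
    n_cv_iterations: int = 1000,
) -> dict:
    """Stability of model selection under balancing of an uneven sex ratio.

    Each repeat randomly subsamples the larger sex down to the smaller
    sex's count and reruns cross-validated selection on the balanced
    sample; returns the fraction of repeats selecting each kind.
    """
    x, y = _check_xy(x, y)
    sex = np.asarray(sex)
    groups = {}
    for label in np.unique(sex):
        groups[label] = np.flatnonzero(sex == label)
    if len(groups) < 2:
        raise ValueError("both sexes must be present")
    smaller = min(groups.values(), key=len)
    larger = max(groups.values(), key=len)
    n_target = len(smaller)
    rng = np.random.default_rng(seed)
    counts = {kind: 0 for kind in MODEL_KINDS}
    for rep in range(n_repeats):
        keep = rng.choice(larger, size=n_target, replace=False)
        idx = np.concatenate([smaller, keep])
        sel = cv_select_model(
            x[idx], y[idx], n_iterations=n_cv_iterations,
            seed=int(rng.integers(2**31 - 1)),
        )
        counts[sel.selected_kind] += 1
    return {kind: counts[kind] / n_repeats for kind in MODEL_KINDS}
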