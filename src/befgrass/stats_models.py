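"""Competing regressions for the diversity-function relationships.

Three models are fitted to each bivariate relationship: ordinary linear,
quadratic, and a continuous one-breakpoint (segmented) model
``y = a + b1 x + (b2 - b1)(x - psi)_+``. The segmented model is estimated by
Muggeo's iteration: at a working breakpoint, refit with the hinge term and a
gap covariate, then update ``psi`` by the ratio of the gap coefficient to the
slope-difference coefficient; the breakpoint SE follows by the delta method.
Davies' test assesses the slope change at an unknown breakpoint (a nuisance
parameter absent under the null) via the upper-bound correction for the
maximal Wald statistic over a candidate grid.

Model competition uses AIC in the Gaussian profile form
``n ln(RSS/n) + 2 (k + 1)`` (k regression parameters including the intercept;
the breakpoint counts as one) with a parsimony rule: if no non-linear model
improves on the linear AIC by at least ``delta_aic`` (default 5) the linear
model wins; otherwise the lowest-AIC model, with a quadratic/piecewise tie
(within the same margin) broken by R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelFitResult",
    "PiecewiseFit",
    "ModelComparison",
    "PiecewiseRegressor",
    "fit_linear",
    "fit_quadratic",
    "fit_piecewise",
    "davies_test",
    "select_best",
    "classify_shape",
    "compare_models",
]

DELTA_AIC_DEFAULT = 5.0


def _aic(rss: float, n: int, k: int) -> float:
    """Gaussian profile AIC, counting sigma^2 as a parameter: n ln(RSS/n) + 2(k+1)."""
    return n * np.log(rss / n) + 2 * (k + 1)


def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with coefficient covariance; returns (coef, cov, rss, dof)."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = n - k
    XtX_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / dof if dof > 0 else np.nan
    return coef, sigma2 * XtX_inv, rss, dof


def _hinge_rss(x: np.ndarray, y: np.ndarray, psi: float) -> float:
    """RSS of y ~ 1 + x + (x - psi)_+ via 3x3 normal equations (fast path)."""
    u = np.clip(x - psi, 0.0, None)
    n = len(x)
    sx, su, sy = x.sum(), u.sum(), y.sum()
    G = np.array([
        [n, sx, su],
        [sx, x @ x, x @ u],
        [su, x @ u, u @ u],
    ])
    b = np.array([sy, x @ y, u @ y])
    try:
        coef = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        return np.inf
    return float(y @ y - coef @ b)


def _gap_update(x: np.ndarray, y: np.ndarray, psi: float) -> float | None:
    """Muggeo update step gamma/beta2 from the 4-parameter gap design."""
    u = np.clip(x - psi, 0.0, None)
    v = -(x > psi).astype(float)
    n = len(x)
    cols = (np.ones(n), x, u, v)
    G = np.array([[a @ b for b in cols] for a in cols])
    rhs = np.array([c @ y for c in cols])
    try:
        coef = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        return None
    if abs(coef[2]) < 1e-12:
        return None
    return coef[3] / coef[2]


@dataclass(frozen=True)
class ModelFitResult:
    """One fitted candidate model on a bivariate relationship."""

    model: str  # linear | quadratic | piecewise
    coef: dict[str, float]
    se: dict[str, float]
    r2: float
    p_overall: float  # overall F-test p
    p_sig: float  # the reported 'Sig.': slope p (linear) / curvature p (quadratic)
    aic: float
    rss: float
    n: int
    x_range: tuple[float, float]
    slope_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError(f"R^2 = {self.r2} outside [0, 1]")


@dataclass(frozen=True)
class PiecewiseFit(ModelFitResult):
    breakpoint: float = float("nan")
    breakpoint_ci: tuple[float, float] = (float("nan"), float("nan"))
    left_slope: float = float("nan")
    left_slope_ci: tuple[float, float] = (float("nan"), float("nan"))
    right_slope: float = float("nan")
    right_slope_ci: tuple[float, float] = (float("nan"), float("nan"))
    davies_p: float | None = None
    converged: bool = True


@dataclass(frozen=True)
class ModelComparison:
    fits: dict[str, ModelFitResult]
    delta_aic: dict[str, float]
    best: str
    shape: str
    trace: tuple[str, ...] = field(default_factory=tuple)
    piecewise_reportable: bool = True  # False -> the '-' row convention


def _check_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    return x, y


def _r2_and_f(rss: float, y: np.ndarray, k_slopes: int) -> tuple[float, float]:
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = max(0.0, 1 - rss / tss) if tss > 0 else 0.0
    n = len(y)
    dof = n - k_slopes - 1
    if rss <= 0 or dof <= 0:
        return min(r2, 1.0), 0.0
    f = (tss - rss) / k_slopes / (rss / dof)
    p = float(stats.f.sf(f, k_slopes, dof))
    return min(r2, 1.0), p


def fit_linear(x, y) -> ModelFitResult:
    x, y = _check_xy(x, y, 3)
    X = np.column_stack([np.ones_like(x), x])
    coef, cov, rss, dof = _ols(X, y)
    r2, p_overall = _r2_and_f(rss, y, 1)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, dof)
    p_slope = 2 * stats.t.sf(abs(coef[1] / se[1]), dof) if se[1] > 0 else 0.0
    return ModelFitResult(
        model="linear",
        coef={"intercept": coef[0], "slope": coef[1]},
        se={"intercept": se[0], "slope": se[1]},
        r2=r2,
        p_overall=p_overall,
        p_sig=float(p_slope),
        aic=_aic(rss, len(x), 2) if rss > 0 else -np.inf,
        rss=rss,
        n=len(x),
        x_range=(float(x.min()), float(x.max())),
        slope_ci=(coef[1] - tcrit * se[1], coef[1] + tcrit * se[1]),
    )


def fit_quadratic(x, y) -> ModelFitResult:
    x, y = _check_xy(x, y, 4)
    if len(np.unique(x)) < 3:
        raise np.linalg.LinAlgError("quadratic design is rank-deficient")
    X = np.column_stack([np.ones_like(x), x, x**2])
    coef, cov, rss, dof = _ols(X, y)
    r2, p_overall = _r2_and_f(rss, y, 2)
    se = np.sqrt(np.diag(cov))
    p_quad = 2 * stats.t.sf(abs(coef[2] / se[2]), dof) if se[2] > 0 else 0.0
    return ModelFitResult(
        model="quadratic",
        coef={"intercept": coef[0], "slope": coef[1], "curvature": coef[2]},
        se={"intercept": se[0], "slope": se[1], "curvature": se[2]},
        r2=r2,
        p_overall=p_overall,
        p_sig=float(p_quad),
        aic=_aic(rss, len(x), 3) if rss > 0 else -np.inf,
        rss=rss,
        n=len(x),
        x_range=(float(x.min()), float(x.max())),
    )


class PiecewiseRegressor(RegressorMixin, BaseEstimator):
    """Continuous one-breakpoint segmented regression.

    Parameters
    ----------
    min_segment : minimum number of observations required strictly on each
        side of the breakpoint (default 5).
    n_starts : number of starting breakpoints (x-quantiles) for Muggeo's
        iteration.
    max_iter : iteration cap per start before declaring non-convergence.
    tol : convergence tolerance on the breakpoint update, as a fraction of
        the x range.
    n_grid : resolution of the profile-RSS grid fallback used when no start
        converges.

    Attributes (after fit)
    ----------------------
    breakpoint_, breakpoint_ci_ : psi and its delta-method 95% CI.
    left_slope_, right_slope_ : segment slopes b1, b2 with CIs in
        ``left_slope_ci_`` / ``right_slope_ci_``.
    intercept_, rss_, r2_, aic_, converged_.
    """

    def __init__(self, min_segment: int = 5, n_starts: int = 10, max_iter: int = 50,
                 tol: float = 1e-8, n_grid: int = 100, ci_method: str = "delta",
                 n_boot: int = 499, random_state: int | None = None):
        self.min_segment = min_segment
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.n_grid = n_grid
        self.ci_method = ci_method
        self.n_boot = n_boot
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _bounds(self, xs: np.ndarray) -> tuple[float, float]:
        m = self.min_segment
        lo, hi = xs[m - 1], xs[-m]
        if not lo < hi:
            raise ValueError(
                f"no interior breakpoint with {m} points per segment (n = {len(xs)})"
            )
        eps = 1e-9 * (xs[-1] - xs[0])
        return lo + eps, hi - eps

    @staticmethod
    def _hinge_fit(x: np.ndarray, y: np.ndarray, psi: float):
        U = np.clip(x - psi, 0.0, None)
        X = np.column_stack([np.ones_like(x), x, U])
        return _ols(X, y)

    def _muggeo(self, x, y, psi0, lo, hi):
        """One Muggeo run with RSS step-halving (damps the oscillation the
        raw update shows on heavily discretized x)."""
        psi = float(psi0)
        span = x.max() - x.min()
        rss_cur = _hinge_rss(x, y, psi)
        if not np.isfinite(rss_cur):
            return None
        for _ in range(self.max_iter):
            step = _gap_update(x, y, psi)
            if step is None:
                return None
            psi_new, rss_new = psi, rss_cur
            for _half in range(12):  # accept the first step that lowers RSS
                cand = float(np.clip(psi + step, lo, hi))
                rss_cand = _hinge_rss(x, y, cand)
                if rss_cand < rss_cur:
                    psi_new, rss_new = cand, rss_cand
                    break
                step /= 2.0
                if abs(step) <= self.tol * span:
                    break
            if abs(psi_new - psi) <= self.tol * span:
                return psi_new
            psi, rss_cur = psi_new, rss_new
        return psi

    def _gap_model_inference(self, x, y, psi):
        """SEs at the solution from the gap-covariate design (Muggeo)."""
        U = np.clip(x - psi, 0.0, None)
        V = -(x > psi).astype(float)
        X = np.column_stack([np.ones_like(x), x, U, V])
        coef, cov, _, dof = _ols(X, y)
        b1, beta2, gamma = coef[1], coef[2], coef[3]
        se_b1 = np.sqrt(cov[1, 1])
        var_b2 = cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]
        se_b2 = np.sqrt(max(var_b2, 0.0))
        se_psi = np.sqrt(cov[3, 3]) / abs(beta2) if abs(beta2) > 0 else np.inf
        return b1, b1 + beta2, se_b1, se_b2, se_psi, dof

    def _bootstrap_ci(self, x, y, psi_hat) -> tuple[float, float]:
        """Percentile CI of the breakpoint from a pairs bootstrap, each
        replicate warm-started at the full-sample estimate."""
        rng = np.random.default_rng(self.random_state)
        n = len(x)
        fast = PiecewiseRegressor(min_segment=self.min_segment, n_starts=4,
                                  max_iter=self.max_iter, tol=self.tol,
                                  n_grid=self.n_grid)
        estimates = []
        for _ in range(self.n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            try:
                xs = np.sort(xb)
                lo, hi = fast._bounds(xs)
                # multistart within each replicate: the replicate's profile
                # RSS can be multimodal, and the warm start alone would
                # understate the resampling variability
                starts = np.clip(
                    np.append(np.quantile(xb, [0.2, 0.45, 0.7, 0.9]), psi_hat), lo, hi
                )
                best_psi, best_rss = None, np.inf
                for psi0 in np.unique(starts):
                    psi = fast._muggeo(xb, yb, float(psi0), lo, hi)
                    if psi is None:
                        continue
                    rss = _hinge_rss(xb, yb, psi)
                    if rss < best_rss:
                        best_psi, best_rss = psi, rss
                if best_psi is None:
                    continue
                estimates.append(best_psi)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if len(estimates) < max(20, self.n_boot // 4):
            raise ValueError("bootstrap breakpoint CI: too few valid replicates")
        lo, hi = np.percentile(estimates, [2.5, 97.5])
        return (float(lo), float(hi))

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("PiecewiseRegressor expects a single feature")
            x = x[:, 0]
        x, y = _check_xy(x, y, max(7, 2 * self.min_segment))
        xs = np.sort(x)
        lo, hi = self._bounds(xs)

        starts = np.quantile(x, np.linspace(0.1, 0.9, self.n_starts))
        starts = np.clip(starts, lo, hi)
        best = None
        for psi0 in np.unique(starts):
            psi = self._muggeo(x, y, psi0, lo, hi)
            if psi is None:
                continue
            try:
                coef, _, rss, _ = self._hinge_fit(x, y, psi)
            except np.linalg.LinAlgError:
                continue
            if best is None or rss < best[1]:
                best = (psi, rss, coef)
        converged = best is not None
        if not converged:  # profile-RSS grid fallback
            grid = np.linspace(lo, hi, self.n_grid)
            for psi in grid:
                try:
                    coef, _, rss, _ = self._hinge_fit(x, y, psi)
                except np.linalg.LinAlgError:
                    continue
                if best is None or rss < best[1]:
                    best = (psi, rss, coef)
            if best is None:
                raise ValueError("piecewise fit failed on every candidate breakpoint")

        psi, rss, coef = best
        b1, b2, se_b1, se_b2, se_psi, dof = self._gap_model_inference(x, y, psi)
        tcrit = stats.t.ppf(0.975, dof)
        self.n_features_in_ = 1
        self.x_ = x
        self.y_ = y
        self.breakpoint_ = float(psi)
        self.breakpoint_se_ = float(se_psi)
        if self.ci_method == "delta":
            self.breakpoint_ci_ = (psi - tcrit * se_psi, psi + tcrit * se_psi)
        elif self.ci_method == "bootstrap":
            self.breakpoint_ci_ = self._bootstrap_ci(x, y, psi)
        else:
            raise ValueError(f"unknown ci_method {self.ci_method!r}")
        self.intercept_ = float(coef[0])
        self.left_slope_ = float(b1)
        self.right_slope_ = float(b2)
        self.left_slope_ci_ = (b1 - tcrit * se_b1, b1 + tcrit * se_b1)
        self.right_slope_ci_ = (b2 - tcrit * se_b2, b2 + tcrit * se_b2)
        self.rss_ = float(rss)
        self.r2_, self.p_overall_ = _r2_and_f(rss, y, 3)
        # k = 4 regression parameters: intercept, two slopes, breakpoint
        self.aic_ = _aic(rss, len(x), 4) if rss > 0 else -np.inf
        self.converged_ = converged
        return self

    def predict(self, X):
        check_is_fitted(self, "breakpoint_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        hinge = np.clip(x - self.breakpoint_, 0.0, None)
        return (self.intercept_ + self.left_slope_ * x
                + (self.right_slope_ - self.left_slope_) * hinge)

    def to_result(self, davies_p: float | None = None) -> PiecewiseFit:
        check_is_fitted(self, "breakpoint_")
        x = self.x_
        return PiecewiseFit(
            model="piecewise",
            coef={"intercept": self.intercept_, "left_slope": self.left_slope_,
                  "right_slope": self.right_slope_, "breakpoint": self.breakpoint_},
            se={"breakpoint": self.breakpoint_se_},
            r2=self.r2_,
            p_overall=self.p_overall_,
            p_sig=self.p_overall_,
            aic=self.aic_,
            rss=self.rss_,
            n=len(x),
            x_range=(float(x.min()), float(x.max())),
            breakpoint=self.breakpoint_,
            breakpoint_ci=self.breakpoint_ci_,
            left_slope=self.left_slope_,
            left_slope_ci=self.left_slope_ci_,
            right_slope=self.right_slope_,
            right_slope_ci=self.right_slope_ci_,
            davies_p=davies_p,
            converged=self.converged_,
        )


def fit_piecewise(x, y, min_segment: int = 5, with_davies: bool = True,
                  ci_method: str = "delta", n_boot: int = 499,
                  seed: int | None = None) -> PiecewiseFit:
    reg = PiecewiseRegressor(min_segment=min_segment, ci_method=ci_method,
                             n_boot=n_boot, random_state=seed).fit(np.asarray(x, float), y)
    davies_p = davies_test(x, y) if with_davies and len(np.asarray(x).ravel()) >= 10 else None
    return reg.to_result(davies_p=davies_p)


def davies_test(x, y, K: int = 10) -> float:
    """Davies' test for a slope change at an unknown breakpoint.

    Signed Wald statistics for the slope-difference coefficient are evaluated
    at K candidate breakpoints equally spaced between the 10th and 90th x
    percentiles; the two-sided p-value combines the maximal statistic with
    Davies' (1987) upper bound, p = 2 Phi(-M) + V exp(-M^2/2) / sqrt(8 pi),
    where V is the total variation of the statistic sequence. Capped at 1.
    """
    x, y = _check_xy(x, y, 10)
    qs = np.quantile(x, [0.10, 0.90])

    def _wald(psis):
        ts, dof = [], None
        for psi in psis:
            U = np.clip(x - psi, 0.0, None)
            X = np.column_stack([np.ones_like(x), x, U])
            try:
                coef, cov, _, dof = _ols(X, y)
            except np.linalg.LinAlgError:
                continue
            se = np.sqrt(cov[2, 2])
            if se > 0:
                ts.append(coef[2] / se)
        return np.array(ts), dof

    ts, dof = _wald(np.linspace(qs[0], qs[1], K))
    if len(ts) == 0:
        raise ValueError("Davies' test: no admissible candidate breakpoints")
    M = float(np.max(np.abs(ts)))
    # the total-variation term needs the statistic's path over the whole
    # interval; a coarse grid understates it, so it is refined here
    ts_fine, _ = _wald(np.linspace(qs[0], qs[1], max(5 * K, 50)))
    total_variation = float(np.abs(np.diff(ts_fine)).sum())
    tail = 2 * stats.t.sf(M, dof) if dof and dof > 0 else 2 * stats.norm.sf(M)
    p = tail + total_variation * np.exp(-(M**2) / 2) / np.sqrt(8 * np.pi)
    return float(min(p, 1.0))


def select_best(
    fits: dict[str, ModelFitResult], delta_aic_threshold: float = DELTA_AIC_DEFAULT
) -> ModelComparison:
    """Apply the AIC parsimony rule to the three candidate fits.

    Models within ``delta_aic_threshold`` AIC units are deemed
    indistinguishable: the linear model wins unless a non-linear model beats
    it by at least the threshold, and a quadratic/piecewise near-tie is
    broken by R^2.
    """
    expected = {"linear", "quadratic", "piecewise"}
    if set(fits) != expected:
        raise ValueError(f"need exactly the fits {sorted(expected)}")
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValueError(f"fits computed on different sample sizes: {ns}")
    aics = {m: f.aic for m, f in fits.items()}
    amin = min(aics.values())
    delta = {m: a - amin for m, a in aics.items()}
    trace = [f"AIC: " + ", ".join(f"{m}={aics[m]:.2f}" for m in sorted(aics))]

    lin = aics["linear"]
    improvements = {m: lin - aics[m] for m in ("quadratic", "piecewise")}
    if max(improvements.values()) < delta_aic_threshold:
        best = "linear"
        trace.append(
            f"no non-linear model improves on linear by >= {delta_aic_threshold}; "
            "parsimony selects linear"
        )
    else:
        contenders = [m for m, imp in improvements.items() if imp >= delta_aic_threshold]
        if len(contenders) == 2 and abs(aics["quadratic"] - aics["piecewise"]) < delta_aic_threshold:
            best = max(contenders, key=lambda m: fits[m].r2)
            trace.append(
                "quadratic and piecewise within the AIC margin; tie broken by R^2 "
                f"-> {best}"
            )
        else:
            best = min(contenders, key=lambda m: aics[m])
            trace.append(f"lowest AIC among decisive non-linear models -> {best}")
    return ModelComparison(
        fits=dict(fits), delta_aic=delta, best=best,
        shape=classify_shape(fits[best]), trace=tuple(trace),
    )


def _ci_label(ci: tuple[float, float]) -> str:
    lo, hi = ci
    if lo > 0:
        return "Increase"
    if hi < 0:
        return "Decrease"
    return "Unchange"


def classify_shape(fit: ModelFitResult) -> str:
    """Human-readable shape label per model family.

    Linear: Increase/Decrease/Unchange from the slope CI against zero.
    Quadratic: U-type (positive curvature) or Unimodal (negative) when the
    vertex lies inside the x-range, otherwise the monotone label.
    Piecewise: '<left> + <right> (psi)' from the per-segment slope CIs.
    """
    if isinstance(fit, PiecewiseFit):
        left = _ci_label(fit.left_slope_ci)
        right = _ci_label(fit.right_slope_ci)
        return f"{left} + {right} ({fit.breakpoint:.2f})"
    if fit.model == "linear":
        return _ci_label(fit.slope_ci)
    if fit.model == "quadratic":
        c = fit.coef["curvature"]
        b = fit.coef["slope"]
        lo, hi = fit.x_range
        vertex = -b / (2 * c) if c != 0 else np.inf
        if c != 0 and lo < vertex < hi:
            return "U-type" if c > 0 else "Unimodal"
        mid = 0.5 * (lo + hi)
        deriv = b + 2 * c * mid
        return "Increase" if deriv > 0 else ("Decrease" if deriv < 0 else "Unchange")
    raise ValueError(f"cannot classify model {fit.model!r}")


def compare_models(
    x, y,
    delta_aic_threshold: float = DELTA_AIC_DEFAULT,
    min_segment: int = 5,
    davies_alpha: float = 0.05,
) -> ModelComparison:
    """Fit all three models, run Davies' test, and apply the selection rule.

    A piecewise row is flagged non-reportable (the dash convention) when
    Davies' test finds no significant slope change *and* the piecewise model
    is not AIC-preferred — the fitted breakpoint is then not interpretable.
    """
    linear = fit_linear(x, y)
    quadratic = fit_quadratic(x, y)
    piecewise = fit_piecewise(x, y, min_segment=min_segment, with_davies=True)
    comp = select_best(
        {"linear": linear, "quadratic": quadratic, "piecewise": piecewise},
        delta_aic_threshold,
    )
    reportable = not (
        (piecewise.davies_p is not None and piecewise.davies_p > davies_alpha)
        and comp.best != "piecewise"
    )
    return replace(comp, piecewise_reportable=reportable)
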