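"""Linear quantile regression for envelope ("filled triangle") analysis.

A line is fitted at quantile tau by minimizing the check loss
``sum rho_tau(y - a - b x)`` with ``rho_tau(u) = u (tau - 1[u < 0])``; slopes
at the 0.95 and 0.05 quantiles trace the upper and lower bound of the
bivariate cloud. Slope standard errors come from a pairs (case-resampling)
bootstrap — appropriate for the heteroscedastic data an envelope implies —
and two-sided p-values from the normal approximation slope / SE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "QuantileFit",
    "QuantileLineRegressor",
    "fit_quantile",
    "bootstrap_quantile",
    "envelope_table",
]

DEFAULT_N_BOOT = 999


@dataclass(frozen=True)
class QuantileFit:
    tau: float
    intercept: float
    slope: float
    se: float | None = None
    p: float | None = None
    n_boot: int | None = None
    n_boot_effective: int | None = None
    seed: int | None = None

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _check_loss(x, y, intercept, slope, tau) -> float:
    u = y - intercept - slope * x
    return float(np.sum(u * (tau - (u < 0))))


def _fit_lp(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    """Exact LP solution of the check-loss problem (fallback path)."""
    n = len(x)
    # variables: a+, a-, b+, b-, u+ (n), u- (n)
    c = np.concatenate([[0, 0, 0, 0], np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1
    A_eq[:, 1] = -1
    A_eq[:, 2] = x
    A_eq[:, 3] = -x
    A_eq[:, 4:4 + n] = np.eye(n)
    A_eq[:, 4 + n:] = -np.eye(n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    a = res.x[0] - res.x[1]
    b = res.x[2] - res.x[3]
    return float(a), float(b)


class QuantileLineRegressor(RegressorMixin, BaseEstimator):
    """Straight-line conditional-quantile estimator.

    Parameters
    ----------
    tau : quantile in (0, 1).
    n_boot : pairs-bootstrap resamples for the slope SE (0 disables).
    random_state : bootstrap seed.

    After ``fit``: ``intercept_``, ``slope_``, ``se_``, ``p_``,
    ``n_boot_effective_`` (degenerate resamples are skipped and logged).
    """

    def __init__(self, tau: float = 0.5, n_boot: int = 0, random_state: int | None = None):
        self.tau = tau
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _point(x: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.QuantReg(y, sm.add_constant(x)).fit(q=tau)
                a, b = float(res.params[0]), float(res.params[1])
                if np.isfinite(a) and np.isfinite(b):
                    return a, b
            except Exception:  # IRLS can fail on degenerate residuals
                pass
        return _fit_lp(x, y, tau)

    def fit(self, X, y):
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("QuantileLineRegressor expects a single feature")
            x = x[:, 0]
        y = np.asarray(y, dtype=float).ravel()
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 20:
            raise ValueError(f"need at least 20 observations, got {len(x)}")
        if np.ptp(x) == 0:
            raise ValueError("x is constant")
        self.n_features_in_ = 1
        self.intercept_, self.slope_ = self._point(x, y, self.tau)
        self.se_ = None
        self.p_ = None
        self.n_boot_effective_ = None
        if self.n_boot:
            rng = np.random.default_rng(self.random_state)
            slopes = []
            skipped = 0
            n = len(x)
            for _ in range(self.n_boot):
                idx = rng.integers(0, n, n)
                xb, yb = x[idx], y[idx]
                if np.ptp(xb) == 0:
                    skipped += 1
                    continue
                try:
                    _, b = self._point(xb, yb, self.tau)
                except Exception:
                    skipped += 1
                    continue
                slopes.append(b)
            if skipped:
                logger.warning("quantile bootstrap: %d degenerate resamples skipped", skipped)
            self.n_boot_effective_ = len(slopes)
            if len(slopes) >= 2:
                self.se_ = float(np.std(slopes, ddof=1))
                if self.se_ > 0:
                    self.p_ = float(2 * stats.norm.sf(abs(self.slope_ / self.se_)))
                else:
                    self.p_ = 0.0 if self.slope_ != 0 else 1.0
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.intercept_ + self.slope_ * x

    def to_result(self) -> QuantileFit:
        check_is_fitted(self, "slope_")
        return QuantileFit(
            tau=self.tau,
            intercept=self.intercept_,
            slope=self.slope_,
            se=self.se_,
            p=self.p_,
            n_boot=self.n_boot or None,
            n_boot_effective=self.n_boot_effective_,
            seed=self.random_state,
        )


def fit_quantile(x, y, tau: float) -> QuantileFit:
    """Point estimate of the tau-quantile line (no bootstrap)."""
    return QuantileLineRegressor(tau=tau).fit(np.asarray(x, float), y).to_result()


def bootstrap_quantile(
    x, y, tau: float, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None
) -> QuantileFit:
    """Quantile line with pairs-bootstrap SE and normal-approximation p."""
    reg = QuantileLineRegressor(tau=tau, n_boot=n_boot, random_state=seed)
    return reg.fit(np.asarray(x, float), y).to_result()


def envelope_table(
    x,
    responses: pd.DataFrame,
    taus: tuple[float, ...] = (0.05, 0.5, 0.95),
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    alpha: float = 0.05,
    x_name: str = "x",
) -> pd.DataFrame:
    """One row per (response column, tau): slope, SE, p, significance mark.

    The ``line_style`` column encodes the plotting convention: 'solid' for
    relationships significant at ``alpha``, 'dashed' otherwise. Per-column
    failures are recorded as NaN rows, never abort the batch.
    """
    x = np.asarray(x, dtype=float)
    rows = []
    for i, col in enumerate(responses.columns):
        y = responses[col].to_numpy(dtype=float)
        for j, tau in enumerate(taus):
            row = {"predictor": x_name, "metric": col, "tau": tau}
            try:
                sub_seed = None if seed is None else seed + 1000 * i + j
                fit = bootstrap_quantile(x, y, tau, n_boot=n_boot, seed=sub_seed)
                row.update(
                    slope=fit.slope, intercept=fit.intercept, se=fit.se, p=fit.p,
                    n_boot_effective=fit.n_boot_effective,
                    significant=bool(fit.p is not None and fit.p < alpha),
                )
                row["line_style"] = "solid" if row["significant"] else "dashed"
            except Exception as exc:
                logger.warning("envelope fit failed for %s tau=%s: %s", col, tau, exc)
                row.update(slope=np.nan, intercept=np.nan, se=np.nan, p=np.nan,
                           n_boot_effective=0, significant=False, line_style="dashed")
            rows.append(row)
    return pd.DataFrame(rows)
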