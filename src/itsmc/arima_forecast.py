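"""Pre-period ARIMA modelling on log counts: fitting, diagnostics,
RMSE-based order selection and out-of-sample forecasting.

Models are estimated by exact Gaussian maximum likelihood in state-space
form (statsmodels).  A constant is included for d = 0 models and omitted
(no drift) for d = 1.  The selection criterion is the root mean squared
one-step-ahead prediction error over the pre-intervention period on the
log scale; forecast standard errors come from the innovation variance and
psi-weights only (parameter-estimation uncertainty excluded).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import pacf as _sm_pacf

__all__ = [
    "ArimaOrder",
    "ArimaFit",
    "SelectionResult",
    "ForecastPath",
    "log_transform",
    "sample_acf",
    "sample_pacf",
    "fit_arima",
    "one_step_rmse",
    "default_grid",
    "select_order",
    "forecast",
]


class ArimaOrder(NamedTuple):
    p: int
    d: int
    q: int


def log_transform(counts, shift: float = 0.0) -> np.ndarray:
    """Elementwise natural log of ``counts + shift``.

    Zero counts require a positive shift; the error message says so.
    """
    x = np.asarray(counts, dtype=float) + shift
    if np.any(x <= 0):
        raise ValueError(
            "counts + shift must be positive everywhere; "
            "pass a positive shift (e.g. 0.5) for series containing zeros"
        )
    return np.log(x)


def sample_acf(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelations at lags 0..max_lag (biased denominator).

    Constant series have undefined correlations; NaN is returned past lag 0
    with a warning.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= max_lag:
        raise ValueError("series length must exceed max_lag")
    if np.ptp(x) == 0:
        warnings.warn("constant series: autocorrelations undefined", stacklevel=2)
        out = np.full(max_lag + 1, np.nan)
        out[0] = 1.0
        return out
    return _sm_acf(x, nlags=max_lag, adjusted=False, fft=False)


def sample_pacf(series, max_lag: int) -> np.ndarray:
    """Sample partial autocorrelations at lags 0..max_lag via the
    Durbin-Levinson recursion on the biased sample ACF."""
    x = np.asarray(series, dtype=float)
    if len(x) <= max_lag:
        raise ValueError("series length must exceed max_lag")
    if np.ptp(x) == 0:
        warnings.warn("constant series: autocorrelations undefined", stacklevel=2)
        out = np.full(max_lag + 1, np.nan)
        out[0] = 1.0
        return out
    return _sm_pacf(x, nlags=max_lag, method="ldb")


@dataclasses.dataclass
class ArimaFit:
    """One fitted ARIMA model on a log-count series.

    ``residuals`` are the one-step-ahead innovations over the usable part of
    the series (the first ``d`` diffuse residuals are dropped).  ``results``
    keeps the underlying statsmodels results object for forecasting.
    """

    order: ArimaOrder
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    constant: float | None
    sigma2: float
    residuals: np.ndarray
    loglik: float
    converged: bool
    log_series: np.ndarray = dataclasses.field(repr=False)
    results: object = dataclasses.field(repr=False, default=None, compare=False)

    def to_dict(self) -> dict:
        return {
            "order": list(self.order),
            "ar_coefs": [float(a) for a in self.ar_coefs],
            "ma_coefs": [float(m) for m in self.ma_coefs],
            "constant": None if self.constant is None else float(self.constant),
            "sigma2": float(self.sigma2),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "one_step_rmse": float(one_step_rmse(self)),
        }


def fit_arima(log_series, order, *, maxiter: int = 500) -> ArimaFit:
    """Fit ARIMA(p,d,q) to a log-count series by exact Gaussian ML.

    Constant included when d = 0, omitted when d = 1 (no drift).
    Initialization is deterministic (statsmodels method-of-moments starts;
    no random restarts), so refitting the same data reproduces the fit.
    """
    y = np.asarray(log_series, dtype=float)
    order = ArimaOrder(*order)
    p, d, q = order
    if min(p, d, q) < 0:
        raise ValueError("ARIMA order components must be non-negative")
    if len(y) <= p + d + q + 1:
        raise ValueError(
            f"series of length {len(y)} too short for ARIMA{tuple(order)}"
        )
    trend = "n" if d > 0 else "c"
    model = ARIMA(y, order=(p, d, q), trend=trend)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(
                method="statespace",
                method_kwargs={"maxiter": maxiter, "disp": 0},
            )
        retvals = getattr(res, "mle_retvals", None)
        if retvals is not None:
            converged = bool(retvals.get("converged", True))
            if not converged:
                # lbfgs line-search aborts (warnflag 2) at an essentially
                # stationary point are convergence in all but name
                gopt = np.asarray(retvals.get("gopt", [np.inf]), dtype=float)
                converged = bool(np.all(np.abs(gopt) < 1e-2))
        if not np.all(np.isfinite(res.params)):
            converged = False
    except Exception:
        return ArimaFit(
            order=order,
            ar_coefs=np.full(p, np.nan),
            ma_coefs=np.full(q, np.nan),
            constant=None,
            sigma2=float("nan"),
            residuals=np.full(max(len(y) - d, 0), np.nan),
            loglik=float("nan"),
            converged=False,
            log_series=y,
        )
    names = list(res.model.param_names)
    constant = float(res.params[names.index("const")]) if "const" in names else None
    return ArimaFit(
        order=order,
        ar_coefs=np.asarray(res.arparams, dtype=float),
        ma_coefs=np.asarray(res.maparams, dtype=float),
        constant=constant,
        sigma2=float(res.params[names.index("sigma2")]),
        residuals=np.asarray(res.resid, dtype=float)[d:],
        loglik=float(res.llf),
        converged=converged,
        log_series=y,
        results=res,
    )


def one_step_rmse(fit: ArimaFit) -> float:
    """Root mean squared one-step-ahead residual (log scale)."""
    if not fit.converged:
        raise ValueError("RMSE undefined for a non-converged fit")
    return float(np.sqrt(np.mean(fit.residuals**2)))


def default_grid() -> list[ArimaOrder]:
    """The 17-candidate default grid: p, q in {0,1,2}, d in {0,1},
    excluding the degenerate (0,0,0)."""
    grid = [
        ArimaOrder(p, d, q)
        for d in (0, 1)
        for p in (0, 1, 2)
        for q in (0, 1, 2)
        if (p, d, q) != (0, 0, 0)
    ]
    return grid


class Candidate(NamedTuple):
    order: ArimaOrder
    rmse: float  # NaN when the fit failed to converge
    converged: bool


@dataclasses.dataclass
class SelectionResult:
    """Outcome of RMSE-based order selection over a candidate grid."""

    candidates: list[Candidate]
    chosen: ArimaOrder
    chosen_fit: ArimaFit

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p": [c.order.p for c in self.candidates],
                "d": [c.order.d for c in self.candidates],
                "q": [c.order.q for c in self.candidates],
                "rmse": [c.rmse for c in self.candidates],
                "converged": [c.converged for c in self.candidates],
                "chosen": [c.order == self.chosen for c in self.candidates],
            }
        )


_TIE_TOL = 1e-9


def select_order(
    pre_log_series, grid: list[ArimaOrder] | None = None
) -> SelectionResult:
    """Fit every candidate order and choose the one minimizing pre-period
    one-step RMSE.

    Non-converged candidates are retained in the report (RMSE = NaN) but
    excluded from selection.  RMSE ties within 1e-9 are broken by parsimony:
    smaller p + q first, then smaller q.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("candidate grid is empty")
    y = np.asarray(pre_log_series, dtype=float)
    candidates: list[Candidate] = []
    fits: dict[ArimaOrder, ArimaFit] = {}
    for order in grid:
        order = ArimaOrder(*order)
        try:
            fit = fit_arima(y, order)
        except ValueError:
            candidates.append(Candidate(order, float("nan"), False))
            continue
        if fit.converged:
            fits[order] = fit
            candidates.append(Candidate(order, one_step_rmse(fit), True))
        else:
            candidates.append(Candidate(order, float("nan"), False))
    if not fits:
        raise RuntimeError("no candidate ARIMA model converged")
    best_rmse = min(c.rmse for c in candidates if c.converged)
    tied = [
        c.order
        for c in candidates
        if c.converged and c.rmse <= best_rmse + _TIE_TOL
    ]
    chosen = min(tied, key=lambda o: (o.p + o.q, o.q, o.p, o.d))
    return SelectionResult(
        candidates=candidates, chosen=chosen, chosen_fit=fits[chosen]
    )


@dataclasses.dataclass
class ForecastPath:
    """Out-of-sample log-scale forecast means and standard errors."""

    horizon: int
    log_means: np.ndarray
    log_ses: np.ndarray

    def __post_init__(self) -> None:
        self.log_means = np.asarray(self.log_means, dtype=float)
        self.log_ses = np.asarray(self.log_ses, dtype=float)
        if self.log_means.shape != (self.horizon,) or self.log_ses.shape != (
            self.horizon,
        ):
            raise ValueError("forecast arrays must have length = horizon")
        if np.any(self.log_ses < 0):
            raise ValueError("forecast standard errors must be non-negative")

    @property
    def median_counts(self) -> np.ndarray:
        """exp(log mean): the median of the implied log-normal count forecast."""
        return np.exp(self.log_means)


def forecast(fit: ArimaFit, pre_log_series=None, horizon: int = 1) -> ForecastPath:
    """Minimum-MSE h-step forecasts with innovation-variance SEs.

    When ``pre_log_series`` differs from the series the model was fitted on,
    the fitted parameters are re-applied to the new series (no refitting).
    """
    if not fit.converged:
        raise ValueError("cannot forecast from a non-converged fit")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if fit.results is None:
        raise ValueError("fit carries no model results; refit before forecasting")
    res = fit.results
    if pre_log_series is not None:
        y = np.asarray(pre_log_series, dtype=float)
        if not np.array_equal(y, fit.log_series):
            res = res.apply(y)
    fc = res.get_forecast(horizon)
    return ForecastPath(
        horizon=horizon,
        log_means=np.asarray(fc.predicted_mean, dtype=float),
        log_ses=np.asarray(fc.se_mean, dtype=float),
    )


def fitted_values(fit: ArimaFit) -> np.ndarray:
    """In-sample one-step-ahead predictions on the log scale (length n - d)."""
    d = fit.order.d
    return fit.log_series[d:] - fit.residuals
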