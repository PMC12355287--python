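"""Discrete-time (person-month) survival modelling via pooled logistic regression.

Follow-up is cut into months: a recipient followed for T months contributes T
rows with an event indicator that is 1 only in the final row and only if the
event occurred.  Logistic regression of that indicator on the mixture index,
covariates and a natural spline in month approximates a Cox proportional
hazards model when monthly risks are small; exp(beta) is reported as an
adjusted hazard ratio (aHR), oriented so aHR > 1 means higher hazard.

The fitted model is logit Pr[event in month t | at risk at t]
= a0 + b1*wqs + g'Z + s(t); the complementary survival-probability
parameterisation differs only in coefficient signs.
"""

from __future__ import annotations

import gc
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

DEFAULT_MAX_MONTHS = 60  # administrative censoring horizon, months


def expand_person_periods(
    recipients: pd.DataFrame,
    duration_col: str = "months",
    event_col: str = "event",
    id_col: str = "id",
    max_months: int = DEFAULT_MAX_MONTHS,
) -> pd.DataFrame:
    """Expand recipient-level follow-up into a person-month table.

    A recipient with an event at month T yields rows t = 1..T with the event
    indicator 1 at t = T only; a recipient censored at T yields T all-zero
    rows.  Follow-up beyond ``max_months`` is administratively censored (any
    later event is dropped, with a log message).  All other columns of
    ``recipients`` are carried onto each person-month row unchanged.

    Returns a DataFrame with columns ``id_col``, ``t``, ``event`` plus the
    carried covariate columns.
    """
    durations = recipients[duration_col].to_numpy()
    if not np.all(durations == durations.astype(int)) or (durations < 1).any():
        raise ValueError("follow-up months must be integers >= 1")
    durations = durations.astype(int)
    events = recipients[event_col].to_numpy().astype(int)
    if max_months < 1:
        raise ValueError("max_months must be >= 1")

    capped = np.minimum(durations, max_months)
    dropped_events = int(np.sum((durations > max_months) & (events == 1)))
    if dropped_events:
        logger.info(
            "administratively censored %d event(s) occurring after month %d",
            dropped_events, max_months,
        )
    events = np.where(durations > max_months, 0, events)

    idx = np.repeat(np.arange(len(recipients)), capped)
    t = np.concatenate([np.arange(1, T + 1) for T in capped]) if len(capped) else \
        np.array([], dtype=int)
    last = np.concatenate([np.arange(1, T + 1) == T for T in capped]) if len(capped) \
        else np.array([], dtype=bool)
    y = np.where(last, events[idx], 0)

    carry = recipients.drop(columns=[duration_col, event_col]).reset_index(drop=True)
    out = carry.iloc[idx].reset_index(drop=True)
    out.insert(loc=1 if id_col in out.columns else 0, column="t", value=t)
    out["event"] = y
    return out


def truncate_followup(ppt: pd.DataFrame, horizon: int = 12) -> pd.DataFrame:
    """Restrict a person-period table to the first ``horizon`` months.

    Rows with t > horizon are dropped; a recipient whose event lies beyond
    the horizon is thereby converted to a censoring at the horizon.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return ppt[ppt["t"] <= horizon].reset_index(drop=True)


def natural_spline_basis(
    t,
    df: int = 4,
    knots=None,
    boundary_knots=None,
    event_times=None,
) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept column).

    Interior knots default to the equally spaced quantiles i/df
    (i = 1..df-1) of ``event_times`` when given, otherwise of ``t`` itself;
    boundary knots default to min/max of ``t``.  The basis is the truncated
    power natural-spline construction: piecewise cubic between the boundary
    knots and exactly linear beyond them.
    """
    t = np.asarray(t, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if boundary_knots is None:
        boundary_knots = (float(np.min(t)), float(np.max(t)))
    lo, hi = boundary_knots
    if not lo < hi:
        raise ValueError("degenerate boundary knots; need at least 2 distinct t")
    if df == 1:
        return t.reshape(-1, 1)
    if knots is None:
        source = np.asarray(event_times, float) if event_times is not None else t
        probs = np.arange(1, df) / df
        knots = np.quantile(source, probs)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(knots) != df - 1:
        raise ValueError(f"need df-1={df - 1} interior knots, got {len(knots)}")
    xi = np.concatenate([[lo], knots, [hi]])
    if len(np.unique(xi)) != len(xi):
        raise ValueError(
            "duplicate knots: too few distinct time values for the requested df; "
            "reduce df or supply knots explicitly"
        )
    K = len(xi)

    def d(k):  # k is 0-based knot index
        return (
            np.clip(t - xi[k], 0, None) ** 3 - np.clip(t - xi[K - 1], 0, None) ** 3
        ) / (xi[K - 1] - xi[k])

    cols = [t]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


@dataclass
class PooledLogisticFit:
    """Result of a pooled logistic (discrete-time hazard) regression."""

    beta1: float
    se1: float
    ci95: tuple[float, float]
    hazard_ratio: float
    hr_ci95: tuple[float, float]
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    n_periods: int
    n_events: int
    spline_df: int
    converged: bool = True
    notes: list = field(default_factory=list)
    spline_kwargs: dict = field(default_factory=dict)


class PooledLogisticHazard(BaseEstimator):
    """Discrete-time proportional-hazards model fit by pooled logistic regression.

    The estimator takes recipient-level data, expands it to person-months
    internally, and fits a logistic model for the monthly event probability
    with a natural-spline baseline in time.

    Parameters
    ----------
    spline_df : int, default 4
        Degrees of freedom of the natural spline in months since transplant.
    max_months : int, default 60
        Administrative censoring horizon.
    exposure_col : str or None
        Column of X whose exp(coefficient) is the headline hazard ratio
        (default: the first column).

    Attributes
    ----------
    coef_ : pd.Series of fitted log-odds coefficients
    hazard_ratio_ : headline aHR per unit of ``exposure_col``
    hr_ci95_ : its Wald 95% CI
    n_periods_, n_events_ : person-months and events used
    result_ : PooledLogisticFit
    """

    def __init__(self, spline_df: int = 4, max_months: int = DEFAULT_MAX_MONTHS,
                 exposure_col: str | None = None):
        self.spline_df = spline_df
        self.max_months = max_months
        self.exposure_col = exposure_col

    def fit(self, X: pd.DataFrame, y):
        """Fit from covariates ``X`` (one row per recipient) and survival ``y``.

        ``y`` is either a structured array with fields ("event", "time") or a
         2-column array-like (event flag, months of follow-up).
        """
        events, durations = _unpack_survival(y)
        X = pd.DataFrame(X).reset_index(drop=True)
        rec = X.copy()
        rec["months"] = durations
        rec["event"] = events
        ppt = expand_person_periods(rec, max_months=self.max_months)
        fit = fit_pooled_logistic(
            ppt,
            exposure_col=self.exposure_col or X.columns[0],
            covariate_cols=[c for c in X.columns
                            if c != (self.exposure_col or X.columns[0])],
            spline_df=self.spline_df,
        )
        self.result_ = fit
        self._spline_kwargs_ = fit.spline_kwargs
        self.coef_ = fit.params
        self.hazard_ratio_ = fit.hazard_ratio
        self.hr_ci95_ = fit.hr_ci95
        self.n_periods_ = fit.n_periods
        self.n_events_ = fit.n_events
        return self

    def predict_hazard(self, X: pd.DataFrame, t) -> np.ndarray:
        """Monthly event probability for covariate rows X at months t."""
        check_is_fitted(self, "result_")
        design = _pooled_design(
            pd.DataFrame(X).assign(t=np.asarray(t)),
            self.result_.params.index,
            self.spline_df,
            self._spline_kwargs_,
        )
        eta = design.to_numpy() @ self.result_.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    # populated by fit via fit_pooled_logistic notes
    _spline_kwargs_: dict = {}


def _unpack_survival(y):
    if isinstance(y, pd.DataFrame):
        return y.iloc[:, 0].to_numpy().astype(int), y.iloc[:, 1].to_numpy().astype(int)
    arr = np.asarray(y)
    if arr.dtype.names:  # structured, sksurv-style
        names = arr.dtype.names
        return arr[names[0]].astype(int), arr[names[1]].astype(int)
    arr = np.atleast_2d(arr)
    return arr[:, 0].astype(int), arr[:, 1].astype(int)


def _spline_colnames(df):
    return [f"spline_t_{k}" for k in range(1, df + 1)]


def _pooled_design(frame, param_index, spline_df, spline_kwargs):
    basis = natural_spline_basis(frame["t"].to_numpy(), df=spline_df, **spline_kwargs)
    design = frame.drop(columns=["t"]).copy()
    for k, name in enumerate(_spline_colnames(spline_df)):
        design[name] = basis[:, k]
    design.insert(0, "const", 1.0)
    return design[list(param_index)]


def fit_pooled_logistic(
    ppt: pd.DataFrame,
    exposure_col: str = "wqs",
    covariate_cols=(),
    spline_df: int = 4,
) -> PooledLogisticFit:
    """Pooled logistic regression on a person-period table.

    Regresses the monthly event indicator on the exposure column, covariates
    and a natural spline in ``t`` (interior knots at quantiles of observed
    event months).  Returns the log discrete-time hazard ratio per unit of
    exposure with a Wald 95% CI, exponentiated to an aHR.
    """
    y = ppt["event"].to_numpy()
    n_events = int(y.sum())
    if n_events == 0:
        raise ValueError("no events in person-period table; cannot fit hazard model")
    t = ppt["t"].to_numpy(dtype=float)
    event_times = t[y == 1]
    spline_kwargs = {
        "boundary_knots": (float(t.min()), float(t.max())),
        "event_times": event_times if len(np.unique(event_times)) >= spline_df else None,
    }
    basis = natural_spline_basis(t, df=spline_df, **spline_kwargs)

    cols = [exposure_col, *covariate_cols]
    design = ppt[cols].astype(float).copy()
    for k, name in enumerate(_spline_colnames(spline_df)):
        design[name] = basis[:, k]
    design = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("singular design matrix in pooled logistic regression")

    model = sm.GLM(y, design, family=sm.families.Binomial())
    res = model.fit(maxiter=200)
    params, bse, cov = res.params, res.bse, res.cov_params()
    converged = res.converged
    res.remove_data()  # person-period designs are large; drop them eagerly
    gc.collect()
    notes = []
    if not converged:
        notes.append("IRLS did not converge")
    if (bse > 50).any():
        notes.append("very large standard errors: possible separation")
        logger.warning("pooled logistic fit flags: %s", notes)

    b1 = float(params[exposure_col])
    se1 = float(bse[exposure_col])
    lo, hi = b1 - 1.959963984540054 * se1, b1 + 1.959963984540054 * se1
    return PooledLogisticFit(
        beta1=b1,
        se1=se1,
        ci95=(lo, hi),
        hazard_ratio=float(np.exp(b1)),
        hr_ci95=(float(np.exp(lo)), float(np.exp(hi))),
        params=params,
        bse=bse,
        cov_params=cov,
        n_periods=int(len(ppt)),
        n_events=n_events,
        spline_df=spline_df,
        converged=converged,
        notes=notes,
        spline_kwargs=spline_kwargs,
    )
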