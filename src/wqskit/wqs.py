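"""Two-stage weighted quantile sum (WQS) regression.

WQS regression estimates the joint association of a correlated exposure
mixture with an outcome.  Each constituent is scored into deciles; stage 1
estimates non-negative constituent weights, constrained to sum to 1, by
maximum likelihood on a training split — repeated over bootstrap resamples
and averaged; stage 2 regresses the outcome on the resulting weighted index
wqs = sum_i w_i d_i in a held-out validation split, so the index coefficient
beta1 is interpreted per simultaneous 1-decile increase in all constituents.

The simplex constraint is handled by a softmax reparameterisation
w = softmax(a), optimised jointly with the unconstrained intercept, index
coefficient and covariate coefficients by L-BFGS with analytic gradients
and random multi-starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .quantile import DecileTransformer
from . import survival as _surv

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


class ConvergenceError(RuntimeError):
    """Constrained stage-1 fit failed to converge from every start."""


@dataclass
class SplitSpec:
    """Reproducible recipient-level train/validation partition."""

    train_fraction: float
    seed: int
    assignment: pd.Series  # id -> "train" | "validation"

    @property
    def train_ids(self):
        return self.assignment.index[self.assignment == "train"]

    @property
    def validation_ids(self):
        return self.assignment.index[self.assignment == "validation"]


@dataclass
class WeightVector:
    """Simplex-constrained constituent weights from the bootstrap stage."""

    w: pd.Series
    n_boot_used: int

    def __post_init__(self):
        v = self.w.to_numpy(dtype=float)
        if (v < -1e-12).any():
            raise ValueError("weights must be non-negative")
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1 within 1e-8")


@dataclass
class WQSFitResult:
    """Stage-2 estimate of the mixture-index effect.

    ``beta1`` is the log odds (binary family) or log discrete-time hazard
    (survival family) per 1-decile increase in the mixture index;
    ``percent_increase`` is the reporting transform 100*(exp(beta1)-1),
    with CI endpoints transformed identically.
    """

    beta1: float
    se1: float
    ci95: tuple[float, float]
    percent_increase: float
    percent_increase_ci: tuple[float, float]
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    weights: WeightVector
    family: str
    nobs: int
    notes: list = field(default_factory=list)

    @property
    def effect_ratio(self) -> float:
        """exp(beta1): aOR (binary) or aHR (survival) per decile."""
        return float(np.exp(self.beta1))


def split_data(ids, train_fraction: float, seed: int) -> SplitSpec:
    """Simple random, reproducible recipient-level train/validation split."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    ids = pd.Index(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids)))
    labels = np.full(len(ids), "validation", dtype=object)
    labels[perm[:n_train]] = "train"
    return SplitSpec(train_fraction, seed, pd.Series(labels, index=ids))


def compute_mixture_index(deciles, w) -> pd.Series:
    """wqs = sum_i w_i d_i per recipient; bounded in [0, q-1]."""
    D = deciles.to_numpy(dtype=float) if isinstance(deciles, pd.DataFrame) else \
        np.asarray(deciles, dtype=float)
    wv = w.w if isinstance(w, WeightVector) else w
    wv = wv.to_numpy(dtype=float) if isinstance(wv, pd.Series) else \
        np.asarray(wv, dtype=float)
    if D.shape[1] != wv.shape[0]:
        raise ValueError(
            f"dimension mismatch: {D.shape[1]} constituents vs {wv.shape[0]} weights"
        )
    index = pd.Index(deciles.index) if isinstance(deciles, pd.DataFrame) else None
    return pd.Series(D @ wv, index=index, name="wqs")


def _neg_loglik_and_grad(theta, D, y, Z, n_w):
    """Bernoulli negative log-likelihood in (softmax logits a, b0, b1, gamma)."""
    a = theta[:n_w]
    b0 = theta[n_w]
    b1 = theta[n_w + 1]
    gamma = theta[n_w + 2:]
    a_shift = a - a.max()
    e = np.exp(a_shift)
    w = e / e.sum()
    idx = D @ w
    eta = b0 + b1 * idx
    if Z is not None:
        eta = eta + Z @ gamma
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    r = expit(eta) - y
    g_b0 = r.sum()
    g_b1 = idx @ r
    g_w = b1 * (D.T @ r)
    # softmax Jacobian: dw/da = diag(w) - w w'
    g_a = w * (g_w - w @ g_w)
    if Z is not None:
        g_gamma = Z.T @ r
        grad = np.concatenate([g_a, [g_b0, g_b1], g_gamma])
    else:
        grad = np.concatenate([g_a, [g_b0, g_b1]])
    return nll, grad


def _neg_loglik_and_grad_direct(theta, D, y, Z, n_w):
    """Same likelihood, parameterised directly in (w, b0, b1, gamma)."""
    w = theta[:n_w]
    b0 = theta[n_w]
    b1 = theta[n_w + 1]
    gamma = theta[n_w + 2:]
    idx = D @ w
    eta = b0 + b1 * idx
    if Z is not None:
        eta = eta + Z @ gamma
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    r = expit(eta) - y
    g_w = b1 * (D.T @ r)
    if Z is not None:
        grad = np.concatenate([g_w, [r.sum(), idx @ r], Z.T @ r])
    else:
        grad = np.concatenate([g_w, [r.sum(), idx @ r]])
    return nll, grad


def _polish_on_simplex(theta_soft, D, y, Z, n_w, maxiter):
    """Refine the softmax solution with an explicitly constrained solver.

    The softmax map cannot reach the simplex boundary exactly, so optima on
    a face (some weights exactly 0) are only approached asymptotically;
    SLSQP with bounds and the sum-to-one constraint lands on them.
    """
    a = theta_soft[:n_w]
    e = np.exp(a - a.max())
    theta0 = np.concatenate([e / e.sum(), theta_soft[n_w:]])
    res = minimize(
        _neg_loglik_and_grad_direct,
        theta0,
        args=(D, y, Z, n_w),
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n_w + [(None, None)] * (len(theta0) - n_w),
        constraints=[{"type": "eq", "fun": lambda th: th[:n_w].sum() - 1.0,
                      "jac": lambda th: np.r_[np.ones(n_w),
                                              np.zeros(len(th) - n_w)]}],
        options={"maxiter": maxiter, "ftol": 1e-12},
    )
    return res


def fit_constrained_glm(
    deciles,
    y,
    covariates=None,
    family: str = "binomial",
    n_starts: int = 5,
    seed: int | None = None,
    tol: float = 1e-8,
    maxiter: int = 500,
):
    """Stage-1 maximum likelihood over the weight simplex.

    Maximises the Bernoulli log-likelihood of ``y`` on
    (b0 + b1 * sum_i w_i d_i + gamma'Z) jointly over the probability simplex
    in ``w`` and unconstrained (b0, b1, gamma).  For the discrete-time
    survival family the caller passes person-month rows (event indicator as
    ``y``, spline basis columns inside ``covariates``); the likelihood is
    identical in form.

    Returns ``(w, beta1, info)`` where ``info`` carries the attained
    log-likelihood, convergence flag and full parameter vector.  Raises
    ConvergenceError if no start converges.
    """
    if family not in ("binomial", "pooled-logistic"):
        raise ValueError(f"unknown family {family!r}")
    D = deciles.to_numpy(dtype=float) if isinstance(deciles, pd.DataFrame) else \
        np.asarray(deciles, dtype=float)
    names = list(deciles.columns) if isinstance(deciles, pd.DataFrame) else \
        [f"c{i}" for i in range(D.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    Z = None
    if covariates is not None:
        Z = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) \
            else np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != len(y):
            raise ValueError("covariates and outcome lengths differ")
    n_w = D.shape[1]
    if n_w == 1:
        # simplex of dimension 0: weight is identically 1
        w = pd.Series([1.0], index=names)
        res = _profile_logistic(D @ np.array([1.0]), y, Z)
        return w, float(np.asarray(res.params)[1]), {
            "loglik": float(res.llf), "converged": True, "n_w": 1,
        }

    rng = np.random.default_rng(seed)
    p0_int = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    base_tail = np.concatenate(
        [[np.log(p0_int / (1 - p0_int)), 0.0],
         np.zeros(Z.shape[1] if Z is not None else 0)]
    )
    best = None
    n_converged = 0
    for s in range(n_starts):
        a0 = np.zeros(n_w) if s == 0 else rng.normal(size=n_w)
        theta0 = np.concatenate([a0, base_tail])
        res = minimize(
            _neg_loglik_and_grad,
            theta0,
            args=(D, y, Z, n_w),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        grad_ok = np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun))
        if res.success or grad_ok:
            n_converged += 1
            if best is None or res.fun < best.fun - 0.0:
                best = res
    if best is None:
        raise ConvergenceError(
            f"constrained fit failed to converge in all {n_starts} starts"
        )
    polished = _polish_on_simplex(best.x, D, y, Z, n_w, maxiter)
    if polished.success and polished.fun <= best.fun:
        w_vec = np.clip(polished.x[:n_w], 0.0, None)
        w_vec = w_vec / w_vec.sum()
        tail = polished.x[n_w:]
        fun = polished.fun
    else:
        a = best.x[:n_w]
        e = np.exp(a - a.max())
        w_vec = e / e.sum()
        tail = best.x[n_w:]
        fun = best.fun
    w = pd.Series(w_vec, index=names)
    beta1 = float(tail[1])
    info = {
        "loglik": -float(fun),
        "converged": True,
        "n_starts_converged": n_converged,
        "params": np.concatenate([w_vec, tail]),
    }
    return w, beta1, info


def _profile_logistic(index, y, Z):
    X = np.column_stack([np.ones_like(index), index]) if Z is None else \
        np.column_stack([np.ones_like(index), index, Z])
    return sm.Logit(y, X).fit(disp=0)


def estimate_bootstrap_weights(
    deciles,
    y,
    covariates=None,
    family: str = "binomial",
    n_bootstrap: int = 100,
    seed: int | None = None,
    groups=None,
    n_starts: int = 5,
    signal_weighted: bool = False,
) -> WeightVector:
    """Bootstrap-averaged simplex weights (stage 1).

    Draws ``n_bootstrap`` resamples with replacement at the recipient level
    (rows, or whole groups of rows when ``groups`` identifies person-months
    of the same recipient), fits the constrained GLM on each, and returns
    the mean of the converged weight vectors renormalised to sum to 1.
    ``signal_weighted=True`` instead weights each bootstrap's vector by
    |beta1| (a sensitivity variant; the default is the plain mean).
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    D = deciles if isinstance(deciles, pd.DataFrame) else pd.DataFrame(deciles)
    y = np.asarray(y).ravel()
    Z = None if covariates is None else np.asarray(covariates, dtype=float)
    if Z is not None and Z.ndim == 1:
        Z = Z[:, None]
    rng = np.random.default_rng(seed)

    if groups is None:
        unit_rows = [np.array([i]) for i in range(len(y))]
    else:
        groups = np.asarray(groups)
        unit_rows = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    n_units = len(unit_rows)

    acc, betas = [], []
    n_failed = 0
    for b in range(n_bootstrap):
        draw = rng.integers(0, n_units, size=n_units)
        rows = np.concatenate([unit_rows[u] for u in draw])
        try:
            w, beta1, _ = fit_constrained_glm(
                D.iloc[rows],
                y[rows],
                None if Z is None else Z[rows],
                family=family,
                n_starts=n_starts,
                seed=int(rng.integers(2**31 - 1)),
            )
        except ConvergenceError:
            n_failed += 1
            continue
        acc.append(w.to_numpy())
        betas.append(abs(beta1))
    if not acc:
        raise ConvergenceError(f"all {n_bootstrap} bootstrap fits failed")
    if n_failed:
        logger.warning("%d of %d bootstrap fits failed to converge and were skipped",
                       n_failed, n_bootstrap)
    W = np.asarray(acc)
    if signal_weighted:
        bw = np.asarray(betas)
        bw = bw / bw.sum() if bw.sum() > 0 else np.full(len(acc), 1.0 / len(acc))
        mean_w = bw @ W
    else:
        mean_w = W.mean(axis=0)
    mean_w = np.clip(mean_w, 0.0, None)
    mean_w = mean_w / mean_w.sum()
    return WeightVector(pd.Series(mean_w, index=D.columns), n_boot_used=len(acc))


def fit_validation_glm(
    index,
    y,
    covariates=None,
    weights: WeightVector | None = None,
    family: str = "binomial",
) -> WQSFitResult:
    """Stage-2 GLM of the outcome on the frozen mixture index (binary family).

    Logistic regression of ``y`` on (wqs, covariates) with a Wald 95% CI on
    the index coefficient; the reporting transform (exp(beta1)-1)*100 and
    its CI are attached.
    """
    idx = np.asarray(index, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    design = pd.DataFrame({"wqs": idx})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        design = pd.concat([design, cov.astype(float)], axis=1)
    design = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("singular design matrix in validation GLM")
    res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
    notes = []
    if not res.converged:
        notes.append("IRLS did not converge")
    if (res.bse > 50).any():
        notes.append(
            "very large standard errors: possible separation — consider pooling "
            "sparse covariate levels or penalised estimation"
        )
        logger.warning("validation GLM flags: %s", notes)
    return _package_stage2(res, "wqs", weights, family, int(len(y)), notes)


def _package_stage2(res, coef_name, weights, family, nobs, notes) -> WQSFitResult:
    params, bse, cov = res.params, res.bse, res.cov_params()
    res.remove_data()  # drop design arrays so repeated fits stay lean
    b1 = float(params[coef_name])
    se1 = float(bse[coef_name])
    lo, hi = b1 - Z975 * se1, b1 + Z975 * se1
    if weights is None:
        weights = WeightVector(pd.Series([1.0], index=["index"]), 0)
    return WQSFitResult(
        beta1=b1,
        se1=se1,
        ci95=(lo, hi),
        percent_increase=float((np.exp(b1) - 1.0) * 100.0),
        percent_increase_ci=(
            float((np.exp(lo) - 1.0) * 100.0),
            float((np.exp(hi) - 1.0) * 100.0),
        ),
        params=params,
        bse=bse,
        cov_params=cov,
        weights=weights,
        family=family,
        nobs=nobs,
        notes=notes,
    )


class WQSRegression(BaseEstimator):
    """Two-stage weighted quantile sum regression, sklearn-style.

    ``fit(X, y, covariates=...)`` takes raw constituent concentrations
    (rows = recipients), scores them into deciles with cut points from the
    full sample, splits recipients into train/validation, bootstrap-estimates
    simplex weights on the training half, and fits the stage-2 model on the
    validation half.

    Parameters
    ----------
    n_quantiles : int, default 10
    n_bootstrap : int, default 100
    train_fraction : float, default 0.4
        Fraction assigned to the stage-1 (training) split.
    family : "binomial" or "pooled-logistic"
        "binomial" expects a binary y; "pooled-logistic" expects y as
        (event, months) pairs and fits discrete-time person-month models in
        both stages, with a natural spline in month.
    spline_df : int, default 4
        Baseline-hazard spline df (survival family only).
    max_months : int, default 60
    adjust_stage1 : bool, default True
        Include the covariates in the stage-1 constrained fits as well.
    signal_weighted_mean : bool, default False
        Weight bootstrap weight vectors by |beta1| instead of the plain mean.
    n_starts : int, default 5
        Random multi-starts per constrained fit.
    random_state : int or None
        Single seed fanned out deterministically to split, bootstrap and
        multi-start streams.

    Attributes
    ----------
    weights_ : pd.Series of simplex constituent weights (stage 1)
    n_boot_used_ : converged bootstrap count
    beta1_, ci95_, percent_increase_ : stage-2 index effect
    effect_ratio_ : exp(beta1): aOR (binary) or aHR (survival) per decile
    result_ : WQSFitResult
    split_ : SplitSpec
    transformer_ : fitted DecileTransformer
    """

    def __init__(
        self,
        n_quantiles: int = 10,
        n_bootstrap: int = 100,
        train_fraction: float = 0.4,
        family: str = "binomial",
        spline_df: int = 4,
        max_months: int = 60,
        adjust_stage1: bool = True,
        signal_weighted_mean: bool = False,
        n_starts: int = 5,
        random_state: int | None = None,
    ):
        self.n_quantiles = n_quantiles
        self.n_bootstrap = n_bootstrap
        self.train_fraction = train_fraction
        self.family = family
        self.spline_df = spline_df
        self.max_months = max_months
        self.adjust_stage1 = adjust_stage1
        self.signal_weighted_mean = signal_weighted_mean
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y, covariates=None):
        X = pd.DataFrame(X)
        seeds = np.random.SeedSequence(self.random_state).generate_state(3) % (2**31)
        self.transformer_ = DecileTransformer(self.n_quantiles).fit(X)
        deciles = self.transformer_.transform(X)
        self.split_ = split_data(X.index, self.train_fraction, int(seeds[0]))
        is_train = (self.split_.assignment == "train").to_numpy()

        cov = None if covariates is None else \
            pd.DataFrame(covariates).reset_index(drop=True)
        dec_r = deciles.reset_index(drop=True)

        if self.family == "binomial":
            yb = np.asarray(y).ravel().astype(float)
            wv = estimate_bootstrap_weights(
                dec_r[is_train],
                yb[is_train],
                None if (cov is None or not self.adjust_stage1) else cov[is_train],
                family="binomial",
                n_bootstrap=self.n_bootstrap,
                seed=int(seeds[1]),
                n_starts=self.n_starts,
                signal_weighted=self.signal_weighted_mean,
            )
            index = compute_mixture_index(dec_r, wv)
            self.result_ = fit_validation_glm(
                index[~is_train],
                yb[~is_train],
                None if cov is None else cov[~is_train],
                weights=wv,
                family="binomial",
            )
        elif self.family == "pooled-logistic":
            events, durations = _surv._unpack_survival(y)
            self.result_ = self._fit_survival(
                dec_r, events, durations, cov, is_train, seeds
            )
        else:
            raise ValueError(f"unknown family {self.family!r}")

        wv = self.result_.weights
        self.weights_ = wv.w
        self.n_boot_used_ = wv.n_boot_used
        self.beta1_ = self.result_.beta1
        self.ci95_ = self.result_.ci95
        self.percent_increase_ = self.result_.percent_increase
        self.effect_ratio_ = self.result_.effect_ratio
        return self

    def _fit_survival(self, deciles, events, durations, cov, is_train, seeds):
        rec = deciles.copy()
        if cov is not None:
            rec = pd.concat([rec, cov], axis=1)
        rec["months"] = durations
        rec["event"] = events
        rec["_rid"] = np.arange(len(rec))
        ppt = _surv.expand_person_periods(
            rec, id_col="_rid", max_months=self.max_months
        )
        tr_ids = np.flatnonzero(is_train)
        ppt_tr = ppt[ppt["_rid"].isin(tr_ids)]
        basis_tr = _surv.natural_spline_basis(
            ppt_tr["t"].to_numpy(dtype=float), df=self.spline_df
        )
        zcols = [] if cov is None else list(cov.columns)
        Z_tr = np.column_stack(
            [basis_tr]
            + ([ppt_tr[zcols].to_numpy(dtype=float)] if zcols and self.adjust_stage1
               else [])
        )
        wv = estimate_bootstrap_weights(
            ppt_tr[deciles.columns],
            ppt_tr["event"].to_numpy(),
            Z_tr,
            family="pooled-logistic",
            n_bootstrap=self.n_bootstrap,
            seed=int(seeds[1]),
            groups=ppt_tr["_rid"].to_numpy(),
            n_starts=self.n_starts,
            signal_weighted=self.signal_weighted_mean,
        )
        ppt_va = ppt[~ppt["_rid"].isin(tr_ids)].copy()
        ppt_va["wqs"] = compute_mixture_index(ppt_va[deciles.columns], wv).to_numpy()
        fit = _surv.fit_pooled_logistic(
            ppt_va, exposure_col="wqs", covariate_cols=zcols,
            spline_df=self.spline_df,
        )
        return WQSFitResult(
            beta1=fit.beta1,
            se1=fit.se1,
            ci95=fit.ci95,
            percent_increase=float((fit.hazard_ratio - 1.0) * 100.0),
            percent_increase_ci=(
                float((fit.hr_ci95[0] - 1.0) * 100.0),
                float((fit.hr_ci95[1] - 1.0) * 100.0),
            ),
            params=fit.params,
            bse=fit.bse,
            cov_params=fit.cov_params,
            weights=wv,
            family="pooled-logistic",
            nobs=fit.n_periods,
            notes=fit.notes,
        )

    def transform(self, X) -> pd.Series:
        """Mixture index for new concentration rows, using frozen cut points."""
        check_is_fitted(self, "weights_")
        deciles = self.transformer_.transform(pd.DataFrame(X))
        return compute_mixture_index(deciles, self.weights_)

    def predict_proba(self, X, covariates=None):
        """Stage-2 event probability for new rows (binomial family only)."""
        check_is_fitted(self, "result_")
        if self.family != "binomial":
            raise NotImplementedError("predict_proba is for the binomial family")
        idx = self.transform(X).to_numpy()
        design = pd.DataFrame({"const": 1.0, "wqs": idx})
        if covariates is not None:
            cov = pd.DataFrame(covariates).reset_index(drop=True)
            for c in cov.columns:
                design[c] = cov[c].to_numpy(dtype=float)
        p1 = expit(design[list(self.result_.params.index)].to_numpy()
                   @ self.result_.params.to_numpy())
        return np.column_stack([1 - p1, p1])
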