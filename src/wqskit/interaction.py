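"""Effect-measure modification: subgroup effects and interaction tests.

A binary modifier (e.g. age >= 55, female sex, non-White race, deceased
donor, cold ischemia time > 12 h) enters the stage-2 model as a main effect
plus a wqs-by-modifier product term, with stage-1 weights left frozen.  The
reference-subgroup effect is exp(beta1); the other subgroup's effect is
exp(beta1 + beta_int), with its CI from the coefficient covariance, and the
interaction is tested by a Wald test on beta_int.  By construction the two
log-effects differ by exactly beta_int.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import survival as _surv
from .wqs import Z975

from scipy.stats import norm


@dataclass
class ModifierSpec:
    """A binary effect modifier with a documented reference level."""

    name: str
    values: np.ndarray  # 0/1 per recipient; 0 is the reference level
    reference_label: str = "0"
    exposed_label: str = "1"

    def __post_init__(self):
        v = np.asarray(self.values)
        if np.isnan(v.astype(float)).any():
            raise ValueError(f"modifier {self.name!r} has missing values")
        levels = np.unique(v)
        if not np.all(np.isin(levels, [0, 1])):
            raise ValueError(f"modifier {self.name!r} must be coded 0/1")
        if len(levels) < 2:
            raise ValueError(f"modifier {self.name!r} is constant")
        self.values = v.astype(float)


@dataclass
class SubgroupResult:
    """Per-subgroup mixture-index effects and the interaction test."""

    modifier: str
    measure: str  # "aOR" or "aHR"
    estimate0: float
    ci0: tuple[float, float]
    estimate1: float
    ci1: tuple[float, float]
    beta_int: float
    se_int: float
    p_interaction: float
    beta1: float

    def as_row(self) -> dict:
        """Flat dict for a Table-3-style report row."""
        return {
            "modifier": self.modifier,
            "measure": self.measure,
            "subgroup0_estimate": self.estimate0,
            "subgroup0_ci_low": self.ci0[0],
            "subgroup0_ci_high": self.ci0[1],
            "subgroup1_estimate": self.estimate1,
            "subgroup1_ci_low": self.ci1[0],
            "subgroup1_ci_high": self.ci1[1],
            "p_interaction": self.p_interaction,
        }


def fit_with_interaction(
    index,
    modifier: ModifierSpec,
    y=None,
    covariates=None,
    family: str = "binomial",
    time_event=None,
    spline_df: int = 4,
    max_months: int = 60,
) -> SubgroupResult:
    """Stage-2 model with a wqs-by-modifier interaction.

    Parameters
    ----------
    index : mixture index per recipient (stage-1 weights frozen).
    modifier : ModifierSpec coded 0/1 over the same recipients.
    y : binary outcome (binomial family).
    time_event : (event, months) pairs (pooled-logistic family).
    covariates : additional adjustment columns.
    """
    idx = np.asarray(index, dtype=float).ravel()
    mod = modifier.values
    if len(mod) != len(idx):
        raise ValueError("modifier and index lengths differ")
    cov = None if covariates is None else pd.DataFrame(covariates).reset_index(drop=True)

    if family == "binomial":
        design = pd.DataFrame({
            "wqs": idx,
            modifier.name: mod,
            f"wqs_x_{modifier.name}": idx * mod,
        })
        if cov is not None:
            design = pd.concat([design, cov.astype(float)], axis=1)
        design = sm.add_constant(design, has_constant="add")
        res = sm.GLM(np.asarray(y, dtype=float).ravel(), design,
                     family=sm.families.Binomial()).fit(maxiter=200)
        params, cov_p = res.params, res.cov_params()
        res.remove_data()
        measure = "aOR"
    elif family == "pooled-logistic":
        events, durations = _surv._unpack_survival(time_event)
        rec = pd.DataFrame({
            "wqs": idx,
            modifier.name: mod,
            f"wqs_x_{modifier.name}": idx * mod,
        })
        if cov is not None:
            rec = pd.concat([rec, cov.astype(float)], axis=1)
        rec["months"] = durations
        rec["event"] = events
        ppt = _surv.expand_person_periods(rec, max_months=max_months)
        fit = _surv.fit_pooled_logistic(
            ppt,
            exposure_col="wqs",
            covariate_cols=[c for c in rec.columns
                            if c not in ("wqs", "months", "event")],
            spline_df=spline_df,
        )
        params, cov_p = fit.params, fit.cov_params
        measure = "aHR"
    else:
        raise ValueError(f"unknown family {family!r}")

    b1 = float(params["wqs"])
    inter = f"wqs_x_{modifier.name}"
    bint = float(params[inter])
    v1 = float(cov_p.loc["wqs", "wqs"])
    vint = float(cov_p.loc[inter, inter])
    c1i = float(cov_p.loc["wqs", inter])
    se1 = np.sqrt(v1)
    se_sum = np.sqrt(v1 + vint + 2.0 * c1i)
    se_int = np.sqrt(vint)
    p_int = float(2.0 * norm.sf(abs(bint) / se_int))
    return SubgroupResult(
        modifier=modifier.name,
        measure=measure,
        estimate0=float(np.exp(b1)),
        ci0=(float(np.exp(b1 - Z975 * se1)), float(np.exp(b1 + Z975 * se1))),
        estimate1=float(np.exp(b1 + bint)),
        ci1=(
            float(np.exp(b1 + bint - Z975 * se_sum)),
            float(np.exp(b1 + bint + Z975 * se_sum)),
        ),
        beta_int=bint,
        se_int=float(se_int),
        p_interaction=p_int,
        beta1=b1,
    )


def subgroup_table(results) -> pd.DataFrame:
    """Assemble SubgroupResults into a Table-3-style DataFrame."""
    return pd.DataFrame([r.as_row() for r in results])
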