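import numpy as np
import pandas as pd
import pytest

from wqskit.exposure import CONSTITUENTS, ConstituentPanel


@pytest.fixture
def flat_panel():
    """Two-year panel for one zip: every constituent 12.0 in 2006, 0.0 in 2005."""
    rows = []
    for year, level in ((2006, 12.0), (2005, 0.0)):
        rows.append({"zip": "01001", "year": year,
                     **{c: level for c in CONSTITUENTS}})
    return ConstituentPanel(pd.DataFrame(rows))


@pytest.fixture
def small_panel():
    """Three zips x two years with distinct random positive levels."""
    rng = np.random.default_rng(7)
    rows = []
    for z in ("01001", "02139", "94110"):
        for year in (2009, 2010):
            rows.append({"zip": z, "year": year,
                         **{c: float(rng.uniform(0.5, 10)) for c in CONSTITUENTS}})
    return ConstituentPanel(pd.DataFrame(rows))


def make_decile_data(n, j, wstar, beta1, seed, prevalence=0.3, n_covs=0):
    """iid decile scores + Bernoulli outcome from the weighted-index model."""
    from scipy.special import expit, logit

    rng = np.random.default_rng(seed)
    D = rng.integers(0, 10, size=(n, j)).astype(float)
    Z = rng.standard_normal((n, n_covs)) if n_covs else None
    lin = beta1 * (D @ wstar)
    if Z is not None:
        lin = lin + Z @ np.linspace(0.2, -0.2, n_covs)
    y = rng.binomial(1, expit(logit(prevalence) - lin.mean() + lin))
    return pd.DataFrame(D, columns=[f"c{i}" for i in range(j)]), y, Z
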