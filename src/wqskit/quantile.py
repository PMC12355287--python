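"""Quantile (decile) scoring of constituent concentrations.

Each constituent is mapped to integer scores ``0 .. q-1`` using empirical
quantile cut points, so a "1-decile increase" in a constituent is a +1 step
in its score.  Cut points are right-closed: a value exactly on a cut point
falls in the lower bin.  Scores are computed from cut points estimated once
on the full analysis sample (fit) and can then be applied to any subset
(transform), so train and validation halves share the same scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


class DecileTransformer(TransformerMixin, BaseEstimator):
    """Score each column into empirical q-quantile bins 0..q-1.

    Parameters
    ----------
    n_quantiles : int, default 10
        Number of bins (10 = deciles).

    Attributes
    ----------
    cut_points_ : ndarray of shape (n_quantiles - 1, n_features)
        Empirical quantile cut points per column, estimated in ``fit``.
    n_features_in_ : int
    feature_names_in_ : ndarray of str, when fitted on a DataFrame.
    degenerate_features_ : list of column identifiers whose cut points are
        all identical (constant columns); their scores are all 0.
    """

    def __init__(self, n_quantiles: int = 10):
        self.n_quantiles = n_quantiles

    def fit(self, X, y=None):
        X_arr, columns = _as_2d(X)
        n, p = X_arr.shape
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        if n < self.n_quantiles:
            raise ValueError(
                f"need at least n_quantiles={self.n_quantiles} samples, got {n}"
            )
        if not np.all(np.isfinite(X_arr)):
            raise ValueError("exposure values must be finite")
        probs = np.arange(1, self.n_quantiles) / self.n_quantiles
        self.cut_points_ = np.quantile(X_arr, probs, axis=0)
        self.n_features_in_ = p
        if columns is not None:
            self.feature_names_in_ = np.asarray(columns, dtype=object)
        self.degenerate_features_ = []
        for j in range(p):
            if np.all(self.cut_points_[:, j] == self.cut_points_[0, j]) and np.all(
                X_arr[:, j] == X_arr[0, j]
            ):
                name = columns[j] if columns is not None else j
                self.degenerate_features_.append(name)
                logger.warning(
                    "constituent %r is constant; all its decile scores are 0", name
                )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "cut_points_")
        X_arr, columns = _as_2d(X)
        if X_arr.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X_arr.shape[1]} features, transformer was fit with "
                f"{self.n_features_in_}"
            )
        scores = np.empty(X_arr.shape, dtype=np.int64)
        for j in range(X_arr.shape[1]):
            # right-closed bins: a value equal to a cut point goes to the lower bin
            scores[:, j] = np.searchsorted(self.cut_points_[:, j], X_arr[:, j],
                                           side="left")
        index = X.index if isinstance(X, pd.DataFrame) else None
        cols = columns if columns is not None else range(X_arr.shape[1])
        return pd.DataFrame(scores, index=index, columns=list(cols))


def _as_2d(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    return arr, None


def quantile_transform(exposures, q: int = 10) -> pd.DataFrame:
    """Fit-and-transform convenience: decile scores of an exposure table."""
    return DecileTransformer(n_quantiles=q).fit_transform(exposures)
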