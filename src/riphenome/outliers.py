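"""Multivariate extreme-strain detection.

A strain can be unremarkable on every single trait yet extreme in the joint
distribution of a correlated trait set.  The squared Mahalanobis distance
``D2 = (x - xbar)' S^{-1} (x - xbar)`` measures that joint deviation; under
multivariate normality D2 is approximately chi-square with df equal to the
number of traits, giving a per-strain outlier p-value.  Strains with
p < alpha are flagged, with a per-trait high/intermediate/low standing
(panel tertiles) to describe the direction of the deviation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin

from .factors import shrink_correlation

__all__ = ["mahalanobis_outliers", "MahalanobisOutlierDetector"]


def _tertile_standing(matrix: pd.DataFrame) -> pd.DataFrame:
    lo = matrix.quantile(1.0 / 3.0, axis=0)
    hi = matrix.quantile(2.0 / 3.0, axis=0)
    standing = pd.DataFrame("intermediate", index=matrix.index,
                            columns=matrix.columns)
    standing = standing.mask(matrix.le(lo, axis=1), "low")
    standing = standing.mask(matrix.gt(hi, axis=1), "high")
    return standing


def _covariance(X: np.ndarray, shrink_if_singular: bool,
                columns) -> np.ndarray:
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    if np.linalg.matrix_rank(S) < S.shape[0] or \
            np.linalg.cond(S) > 1e12:
        if not shrink_if_singular:
            raise ValueError("singular covariance matrix "
                             "(enable shrinkage or drop traits)")
        sd = X.std(axis=0, ddof=1)
        R = shrink_correlation(pd.DataFrame(X, columns=columns)).matrix
        S = R.to_numpy() * np.outer(sd, sd)
    return S


def mahalanobis_outliers(matrix: pd.DataFrame, alpha: float = 0.05,
                         leave_one_out: bool = False,
                         shrink_if_singular: bool = True) -> pd.DataFrame:
    """Mahalanobis-distance outlier report for a strain-by-trait matrix.

    Uses complete-case strains for the selected traits.  By default the mean
    and covariance include the candidate strain; ``leave_one_out=True``
    recomputes both without it.  Returns a DataFrame indexed by strain with
    ``D2``, ``p`` (upper chi-square tail, df = number of traits), ``flagged``
    and one ``standing_<trait>`` column per trait.
    """
    complete = matrix.dropna()
    n, p = complete.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete strains "
                         f"for {p} traits, got {n}")
    X = complete.to_numpy(dtype=float)

    if leave_one_out:
        d2 = np.empty(n)
        for i in range(n):
            rest = np.delete(X, i, axis=0)
            S = _covariance(rest, shrink_if_singular, complete.columns)
            diff = X[i] - rest.mean(axis=0)
            d2[i] = float(diff @ np.linalg.solve(S, diff))
    else:
        S = _covariance(X, shrink_if_singular, complete.columns)
        diff = X - X.mean(axis=0)
        d2 = np.einsum("ij,ij->i", diff, np.linalg.solve(S, diff.T).T)

    pvals = stats.chi2.sf(d2, df=p)
    report = pd.DataFrame({"D2": d2, "p": pvals,
                           "flagged": pvals < alpha},
                          index=complete.index)
    standing = _tertile_standing(complete)
    standing.columns = [f"standing_{c}" for c in standing.columns]
    return pd.concat([report, standing], axis=1)


class MahalanobisOutlierDetector(BaseEstimator, OutlierMixin):
    """Chi-square Mahalanobis outlier detector with sklearn semantics.

    ``fit`` estimates the location and covariance of the panel (shrinkage
    covariance when the sample covariance is singular); ``predict`` returns
    -1 for strains whose D2 exceeds the chi-square(1 - alpha, df) criterion
    and +1 otherwise.  ``score_samples`` returns negative D2 so that lower
    scores are more anomalous.
    """

    def __init__(self, alpha: float = 0.05, shrink_if_singular: bool = True):
        self.alpha = alpha
        self.shrink_if_singular = shrink_if_singular

    def fit(self, X, y=None) -> "MahalanobisOutlierDetector":
        X = pd.DataFrame(X).dropna()
        n, p = X.shape
        if n < p + 2:
            raise ValueError("need at least p + 2 complete observations")
        self.location_ = X.mean(axis=0).to_numpy()
        self.covariance_ = _covariance(X.to_numpy(dtype=float),
                                       self.shrink_if_singular, X.columns)
        self.n_features_in_ = p
        self.threshold_ = float(stats.chi2.isf(self.alpha, df=p))
        return self

    def mahalanobis(self, X) -> np.ndarray:
        diff = pd.DataFrame(X).to_numpy(dtype=float) - self.location_
        return np.einsum("ij,ij->i", diff,
                         np.linalg.solve(self.covariance_, diff.T).T)

    def score_samples(self, X) -> np.ndarray:
        return -self.mahalanobis(X)

    def predict(self, X) -> np.ndarray:
        return np.where(self.mahalanobis(X) > self.threshold_, -1, 1)
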