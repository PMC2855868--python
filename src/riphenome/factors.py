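"""Multi-trait latent-factor pipeline for n < p strain phenome matrices.

A strain-by-trait matrix from a phenome survey typically has more traits
than strains, so the sample correlation matrix is singular.  The pipeline
(1) removes strains with more than 25% of traits missing, (2) fills the
remaining gaps by column-mean imputation, (3) estimates a James-Stein-type
shrinkage correlation matrix (Schafer-Strimmer analytic intensity, identity
target) that is positive definite even for n < p, (4) chooses the number of
factors by Horn's parallel analysis and/or the optimal-coordinates
criterion, (5) fits an *unrotated* maximum-likelihood factor model by EM,
and (6) produces regression (Thomson) factor scores per strain,
``F = Z R^{-1} Lambda``, which downstream feed the QTL scanner as ordinary
strain means.

`FactorAnalysisPipeline` packages the whole chain as a scikit-learn style
transformer; the module functions expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import FactorModel

__all__ = [
    "ShrunkCorrelation", "filter_strains", "impute_column_means",
    "shrink_correlation", "select_n_factors", "ml_factor_analysis",
    "factor_scores", "variance_explained_report", "strain_profiles",
    "FactorAnalysisPipeline",
]


def filter_strains(matrix: pd.DataFrame, max_missing_fraction: float = 0.25,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Drop strains with strictly more than ``max_missing_fraction`` of
    traits missing; returns the filtered matrix and the removed strain ids."""
    frac = matrix.isna().mean(axis=1)
    removed = matrix.index[frac > max_missing_fraction].tolist()
    kept = matrix.drop(index=removed)
    if len(kept) == 0:
        raise ValueError("all strains removed by the missingness filter")
    return kept, removed


def impute_column_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells by the trait's mean over observed strains."""
    all_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(all_missing) > 0:
        raise ValueError(f"traits with no observed values: "
                         f"{list(all_missing)}")
    return matrix.fillna(matrix.mean(axis=0))


def _standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    sd = matrix.std(axis=0, ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = list(matrix.columns[(sd == 0) | sd.isna()])
        raise ValueError(f"constant or empty traits: {bad}")
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass
class ShrunkCorrelation:
    """Shrinkage correlation matrix with its analytic intensity lambda."""

    matrix: pd.DataFrame
    shrinkage: float

    def __post_init__(self) -> None:
        eig = np.linalg.eigvalsh(self.matrix.to_numpy())
        self.min_eigenvalue = float(eig.min())


def shrink_correlation(matrix: pd.DataFrame) -> ShrunkCorrelation:
    """James-Stein-type shrinkage of the correlation matrix toward identity.

    The analytic intensity is the Schafer-Strimmer form
    ``lambda* = sum_{i!=j} Var(r_ij) / sum_{i!=j} r_ij^2`` clipped to [0, 1],
    with ``Var(r_ij) = n/(n-1)^3 * sum_k (w_kij - w_bar_ij)^2`` computed from
    the products of standardized observations.  The result is positive
    definite whenever ``lambda* > 0``, covering the n < p regime.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("need at least three strains")
    Z = _standardize(matrix).to_numpy()
    p = Z.shape[1]
    wbar = (Z.T @ Z) / n                      # mean of w_kij over k
    R = wbar * n / (n - 1)                    # sample correlation
    Z2 = Z ** 2
    sum_w2 = Z2.T @ Z2
    var_r = n / (n - 1.0) ** 3 * (sum_w2 - n * wbar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = float((R[off] ** 2).sum())
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom,
                                               0.0, 1.0))
    shrunk = (1.0 - lam) * R + lam * np.eye(p)
    np.fill_diagonal(shrunk, 1.0)
    return ShrunkCorrelation(
        matrix=pd.DataFrame(shrunk, index=matrix.columns,
                            columns=matrix.columns),
        shrinkage=lam)


def select_n_factors(matrix: pd.DataFrame, n_reps: int = 100,
                     quantile: float = 0.95, seed: int = 0,
                     ) -> dict[str, int]:
    """Number-of-factors criteria on the sample correlation eigenvalues.

    Parallel analysis (Horn's procedure with the now-standard 95th-centile
    reference): retain leading eigenvalues exceeding the corresponding
    quantile of eigenvalues from seed-fixed random normal data of the same
    n x p (``quantile=None`` uses the mean reference).  Optimal coordinates
    (Raiche): retain while the eigenvalue exceeds both the linear
    extrapolation through the next and the last eigenvalue and the parallel
    reference.  Counting stops at the first failure.  Single-variable data
    force k = 0.
    """
    n, p = matrix.shape
    if p < 2:
        return {"parallel_analysis": 0, "optimal_coordinates": 0}
    Z = _standardize(impute_column_means(matrix)).to_numpy()
    eig = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]

    rng = np.random.default_rng(seed)
    rand = np.empty((n_reps, p))
    for b in range(n_reps):
        X = rng.standard_normal((n, p))
        rand[b] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    ref = (rand.mean(axis=0) if quantile is None
           else np.quantile(rand, quantile, axis=0))
    k_pa = 0
    for i in range(p):
        if eig[i] > ref[i]:
            k_pa += 1
        else:
            break

    k_oc = 0
    for i in range(p - 2):
        slope = (eig[p - 1] - eig[i + 1]) / ((p - 1) - (i + 1))
        predicted = eig[i + 1] + slope * (i - (i + 1))
        if eig[i] > predicted and eig[i] > ref[i]:
            k_oc += 1
        else:
            break
    return {"parallel_analysis": k_pa, "optimal_coordinates": k_oc}


def ml_factor_analysis(R: ShrunkCorrelation | pd.DataFrame | np.ndarray,
                       k: int, tol: float = 1e-8, max_iter: int = 2000,
                       psi_floor: float = 1e-3) -> FactorModel:
    """Unrotated maximum-likelihood factor analysis of a correlation matrix.

    EM with principal-axis eigendecomposition initialization; converges when
    the log-likelihood gain drops below ``tol``.  No rotation is applied;
    factors are ordered by variance explained (column sums of squared
    loadings over p) and each column's sign is fixed so its largest-|loading|
    entry is positive.  Uniquenesses hitting the floor are flagged as
    Heywood cases.
    """
    if isinstance(R, ShrunkCorrelation):
        Rm = R.matrix
    elif isinstance(R, np.ndarray):
        Rm = pd.DataFrame(R)
    else:
        Rm = R
    S = Rm.to_numpy(dtype=float)
    p = S.shape[0]
    if not 0 < k < p:
        raise ValueError("need 0 < k < number of traits")

    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("correlation matrix must be positive definite")
    # squared-multiple-correlation start: psi0 = 1/diag(S^-1), loadings from
    # the eigenstructure of Psi^-1/2 S Psi^-1/2 (factanal-style); for an
    # identity matrix this starts -- and stays -- at the null model
    psi = np.clip(1.0 / np.diag(np.linalg.inv(S)), psi_floor, 1.0)
    sqrt_psi = np.sqrt(psi)
    evals, evecs = np.linalg.eigh(S / np.outer(sqrt_psi, sqrt_psi))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = sqrt_psi[:, None] * evecs[:, :k] \
        * np.sqrt(np.maximum(evals[:k] - 1.0, 0.0))

    ll_path = []
    ll_prev = -np.inf
    converged = False
    eye_k = np.eye(k)
    for _ in range(max_iter):
        sigma = lam @ lam.T + np.diag(psi)
        L = np.linalg.cholesky(sigma)
        sigma_inv = np.linalg.inv(sigma)
        ll = -0.5 * (2.0 * np.log(np.diag(L)).sum()
                     + np.trace(sigma_inv @ S))
        ll_path.append(ll)
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        beta = lam.T @ sigma_inv                       # k x p
        ezz = eye_k - beta @ lam + beta @ S @ beta.T   # k x k
        lam = S @ beta.T @ np.linalg.inv(ezz)
        psi = np.clip(np.diag(S - lam @ (beta @ S)), psi_floor, None)

    heywood = tuple(Rm.index[psi <= psi_floor + 1e-12])
    # canonical identification: the likelihood fixes Lambda only up to an
    # orthogonal rotation, so impose the standard constraint that
    # Lambda' Psi^-1 Lambda is diagonal (the "unrotated" ML solution)
    if (lam ** 2).sum() > 0:
        M = (lam / psi[:, None]).T @ lam
        mvals, Q = np.linalg.eigh(M)
        lam = lam @ Q[:, np.argsort(mvals)[::-1]]
    # at the ML solution diag(Sigma) = diag(S) = 1 exactly; enforce it so
    # the reported communalities and uniquenesses are consistent
    psi = np.clip(np.diag(S) - (lam ** 2).sum(axis=1), psi_floor, None)
    ss = (lam ** 2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    lam = lam[:, order]
    signs = np.sign(lam[np.abs(lam).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    lam = lam * signs
    var_exp = (lam ** 2).sum(axis=0) / p

    loadings = pd.DataFrame(lam, index=Rm.index,
                            columns=[f"F{i + 1}" for i in range(k)])
    return FactorModel(
        loadings=loadings,
        uniquenesses=pd.Series(psi, index=Rm.index, name="uniqueness"),
        variance_explained=var_exp,
        cumulative_variance=np.cumsum(var_exp),
        n_factors=k, loglik_path=np.asarray(ll_path),
        converged=converged, heywood=heywood)


def factor_scores(Z: pd.DataFrame, model: FactorModel,
                  R: ShrunkCorrelation | pd.DataFrame) -> pd.DataFrame:
    """Regression (Thomson) factor scores ``F = Z R^{-1} Lambda``.

    ``Z`` must be standardized with the statistics the correlation matrix was
    built from; ``R`` should be the shrunk correlation (guaranteed
    invertible for n < p).
    """
    Rm = R.matrix if isinstance(R, ShrunkCorrelation) else R
    lam = model.loadings.to_numpy()
    W = np.linalg.solve(Rm.to_numpy(), lam)
    return pd.DataFrame(Z.to_numpy() @ W, index=Z.index,
                        columns=model.loadings.columns)


def variance_explained_report(model: FactorModel,
                              variance_floor: float = 0.013) -> pd.DataFrame:
    """Per-factor and cumulative variance fractions with exclusion flags.

    Factors explaining less than the floor (default 1.3% of total variance)
    are marked excluded from interpretation output.
    """
    return pd.DataFrame({
        "factor": model.loadings.columns,
        "variance_explained": model.variance_explained,
        "cumulative": model.cumulative_variance,
        "excluded": model.variance_explained < variance_floor,
    }).set_index("factor")


def strain_profiles(scores: pd.DataFrame, first_k: int = 8) -> pd.DataFrame:
    """Per-strain profile over the first k factors (radar-plot data)."""
    return scores.iloc[:, :min(first_k, scores.shape[1])].copy()


class FactorAnalysisPipeline(BaseEstimator, TransformerMixin):
    """Strain filtering, imputation, shrinkage FA and factor scores.

    A scikit-learn style transformer over a strain-by-trait DataFrame.
    ``fit`` learns the trait means/SDs, the shrunk correlation matrix and
    the unrotated ML factor model on the retained strains; ``transform``
    returns Thomson factor scores for (possibly new) strains on the fitted
    scale.

    Parameters
    ----------
    n_factors : int or {"parallel_analysis", "optimal_coordinates"}
        Number of factors, or the selection criterion used to choose it.
    max_missing_fraction : float
        Strains missing strictly more than this fraction of traits are
        dropped during fit.
    variance_floor : float
        Factors below this variance fraction are flagged excluded in
        ``variance_report_``.
    random_state : int
        Seed for the parallel-analysis reference eigenvalues.
    """

    def __init__(self, n_factors: int | str = "parallel_analysis",
                 max_missing_fraction: float = 0.25,
                 variance_floor: float = 0.013,
                 random_state: int = 0, tol: float = 1e-8,
                 max_iter: int = 2000):
        self.n_factors = n_factors
        self.max_missing_fraction = max_missing_fraction
        self.variance_floor = variance_floor
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y=None) -> "FactorAnalysisPipeline":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
        kept, removed = filter_strains(X, self.max_missing_fraction)
        self.removed_strains_ = removed
        imputed = impute_column_means(kept)
        self.means_ = imputed.mean(axis=0)
        self.scales_ = imputed.std(axis=0, ddof=1)
        Z = _standardize(imputed)
        shrunk = shrink_correlation(imputed)
        self.correlation_ = shrunk.matrix
        self.shrinkage_ = shrunk.shrinkage
        self.n_factor_criteria_ = select_n_factors(
            imputed, seed=self.random_state)
        if isinstance(self.n_factors, str):
            k = max(1, self.n_factor_criteria_[self.n_factors])
        else:
            k = int(self.n_factors)
        self.n_factors_ = k
        self.model_ = ml_factor_analysis(shrunk, k, tol=self.tol,
                                         max_iter=self.max_iter)
        self.loadings_ = self.model_.loadings
        self.uniquenesses_ = self.model_.uniquenesses
        self.variance_explained_ = self.model_.variance_explained
        self.variance_report_ = variance_explained_report(
            self.model_, self.variance_floor)
        self.scores_ = factor_scores(Z, self.model_, shrunk)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "model_"):
            raise RuntimeError("pipeline is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=self.means_.index)
        X = X.reindex(columns=self.means_.index)
        Z = (X.fillna(self.means_) - self.means_) / self.scales_
        return factor_scores(Z, self.model_, self.correlation_)
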