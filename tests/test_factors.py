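"""Factor pipeline: missingness filter, imputation, shrinkage correlation,
factor-count selection, unrotated ML factor analysis and factor scores."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import riphenome as rp
from riphenome.factors import ShrunkCorrelation, _standardize


def _congruence(A: np.ndarray, B: np.ndarray) -> float:
    """Tucker congruence of best-matched columns (sign-invariant)."""
    k = A.shape[1]
    best = 0.0
    for perm in permutations(range(k)):
        worst = 1.0
        for a, b in zip(range(k), perm):
            num = abs(A[:, a] @ B[:, b])
            den = np.sqrt((A[:, a] ** 2).sum() * (B[:, b] ** 2).sum())
            worst = min(worst, num / den)
        best = max(best, worst)
    return best


class TestFilterAndImpute:
    def test_strict_quarter_boundary(self):
        m = pd.DataFrame(np.zeros((3, 100)), index=["keep", "edge", "drop"])
        m.iloc[1, :25] = np.nan          # exactly 25% -> retained
        m.iloc[2, :26] = np.nan          # 26% -> removed
        kept, removed = rp.filter_strains(m)
        assert removed == ["drop"]
        assert list(kept.index) == ["keep", "edge"]

    def test_complete_matrix_unchanged(self):
        m = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        kept, removed = rp.filter_strains(m)
        pd.testing.assert_frame_equal(kept, m)
        assert removed == []

    def test_panel_fixture_sixty_three_of_ninety_five(self):
        # 95 strains, 32 constructed above the missingness threshold
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(95, 40)),
                         index=[f"BXD{i}" for i in range(95)])
        m = rp.inject_missing(m, 0.0,
                              strain_dropout=[f"BXD{i}" for i in range(32)],
                              seed=1)
        kept, removed = rp.filter_strains(m)
        assert len(removed) == 32 and len(kept) == 63

    def test_all_removed_errors(self):
        m = pd.DataFrame(np.nan, index=["a"], columns=["t1", "t2"])
        with pytest.raises(ValueError):
            rp.filter_strains(m)

    def test_impute_fills_with_observed_means(self):
        m = pd.DataFrame({"t1": [1.0, 2.0, np.nan], "t2": [1.0, 1.0, 1.0]})
        out = rp.impute_column_means(m)
        assert out.loc[2, "t1"] == 1.5
        pd.testing.assert_series_equal(out.mean(), m.mean())

    def test_impute_identity_and_error(self):
        m = pd.DataFrame(np.ones((3, 2)))
        pd.testing.assert_frame_equal(rp.impute_column_means(m), m)
        m[0] = np.nan
        with pytest.raises(ValueError, match="0"):
            rp.impute_column_means(m)


class TestShrinkage:
    def test_matches_brute_force_estimator(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(5, 20)))
        sc = rp.shrink_correlation(X)
        Z = _standardize(X).to_numpy()
        n, p = Z.shape
        num = den = 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                w = Z[:, i] * Z[:, j]
                num += n / (n - 1.0) ** 3 * ((w - w.mean()) ** 2).sum()
                den += (n / (n - 1.0) * w.mean()) ** 2
        assert sc.shrinkage == pytest.approx(min(1.0, num / den), abs=1e-10)
        assert sc.min_eigenvalue > 0.0       # invertible despite n < p

    def test_intensity_vanishes_with_large_n(self):
        # with real correlation structure the sampling-variance numerator
        # shrinks with n while the correlations persist, so lambda* -> 0
        rng = np.random.default_rng(6)
        lams = []
        for n in (20, 200, 2000):
            f = rng.normal(size=(n, 1))
            X = pd.DataFrame(f + rng.normal(size=(n, 5)))
            lams.append(rp.shrink_correlation(X).shrinkage)
        assert lams[0] > lams[1] > lams[2]
        assert lams[2] < 0.02

    def test_uncorrelated_data_shrink_fully(self):
        # all off-diagonal correlations ~ 0 -> lambda* clips to 1
        rng = np.random.default_rng(60)
        X = pd.DataFrame(rng.normal(size=(5, 8)))
        sc = rp.shrink_correlation(X)
        if sc.shrinkage == 1.0:
            assert np.allclose(sc.matrix.to_numpy(), np.eye(8))

    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(10, 15)))
        M = rp.shrink_correlation(X).matrix.to_numpy()
        assert np.allclose(np.diag(M), 1.0)
        assert np.allclose(M, M.T)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            rp.shrink_correlation(X)


class TestFactorCountSelection:
    def test_null_data_retain_at_most_one(self):
        rng = np.random.default_rng(8)
        ok = 0
        for rep in range(20):
            X = pd.DataFrame(rng.normal(size=(100, 20)))
            ks = rp.select_n_factors(X, seed=rep)
            ok += ks["parallel_analysis"] <= 1 and \
                ks["optimal_coordinates"] <= 1
        assert ok >= 19          # k <= 1 in >= 95% of replicates

    def test_three_factor_structure_recovered(self):
        rng = np.random.default_rng(9)
        hits_pa = hits_oc = 0
        n_rep = 25
        for rep in range(n_rep):
            F = rng.normal(size=(100, 3))
            lam = np.zeros((30, 3))
            for j in range(3):
                lam[j * 10:(j + 1) * 10, j] = 0.8
            Z = F @ lam.T + rng.normal(size=(100, 30)) * np.sqrt(1 - 0.64)
            ks = rp.select_n_factors(pd.DataFrame(Z), seed=rep)
            hits_pa += ks["parallel_analysis"] == 3
            hits_oc += ks["optimal_coordinates"] == 3
        assert hits_pa / n_rep >= 0.90
        assert hits_oc / n_rep >= 0.90

    def test_single_variable_forces_zero(self):
        X = pd.DataFrame({"only": [1.0, 2.0, 3.0]})
        ks = rp.select_n_factors(X)
        assert ks == {"parallel_analysis": 0, "optimal_coordinates": 0}


class TestMLFactorAnalysis:
    def _traits(self, p):
        return [f"t{i}" for i in range(p)]

    def test_identity_correlation_yields_null_model(self):
        R = pd.DataFrame(np.eye(12), index=self._traits(12),
                         columns=self._traits(12))
        model = rp.ml_factor_analysis(R, 3)
        assert np.abs(model.loadings.to_numpy()).max() < 0.05
        assert np.all(model.uniquenesses > 0.95)
        assert model.variance_explained.sum() < 0.01

    def test_exact_structure_recovered(self):
        lam = np.zeros((10, 2))
        lam[:5, 0], lam[5:, 1] = 0.8, 0.7
        psi = 1.0 - (lam ** 2).sum(axis=1)
        R = pd.DataFrame(lam @ lam.T + np.diag(psi),
                         index=self._traits(10), columns=self._traits(10))
        model = rp.ml_factor_analysis(R, 2)
        assert _congruence(model.loadings.to_numpy(), lam) > 0.99
        # unit diagonal of Lambda Lambda' + Psi on the correlation scale
        recon = model.loadings.to_numpy() @ model.loadings.to_numpy().T
        diag = np.diag(recon) + model.uniquenesses.to_numpy()
        assert diag == pytest.approx(np.ones(10), abs=1e-6)

    def test_likelihood_monotone_over_em(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(40, 8))
        R = pd.DataFrame(np.corrcoef(X, rowvar=False),
                         index=self._traits(8), columns=self._traits(8))
        model = rp.ml_factor_analysis(R, 2)
        assert np.all(np.diff(model.loglik_path) >= -1e-10)
        assert model.converged

    def test_sigma_matches_sklearn_reference(self):
        # same implied covariance as sklearn's ML factor analysis
        # (loadings agree only up to rotation, so compare Sigma)
        from sklearn.decomposition import FactorAnalysis
        rng = np.random.default_rng(11)
        F = rng.normal(size=(500, 2))
        lam = np.zeros((8, 2))
        lam[:4, 0], lam[4:, 1] = 0.85, 0.75
        X = F @ lam.T + rng.normal(size=(500, 8)) * 0.5
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        R = pd.DataFrame(np.corrcoef(Z, rowvar=False),
                         index=self._traits(8), columns=self._traits(8))
        ours = rp.ml_factor_analysis(R, 2)
        sk = FactorAnalysis(n_components=2, rotation=None,
                            random_state=0).fit(Z)
        sigma_ours = ours.loadings.to_numpy() @ ours.loadings.to_numpy().T \
            + np.diag(ours.uniquenesses)
        sigma_sk = sk.components_.T @ sk.components_ \
            + np.diag(sk.noise_variance_)
        assert np.abs(sigma_ours - sigma_sk).max() < 0.02

    def test_heywood_case_floored_and_flagged(self):
        # a trait nearly collinear with the factor drives its uniqueness
        # below the floor; the estimate is clipped and the trait flagged
        lam = np.full((6, 1), 0.6)
        lam[0, 0] = 0.999
        psi = np.clip(1.0 - (lam ** 2).sum(axis=1), 1e-6, None)
        R = pd.DataFrame(lam @ lam.T + np.diag(psi),
                         index=self._traits(6), columns=self._traits(6))
        np.fill_diagonal(R.to_numpy(), 1.0)
        model = rp.ml_factor_analysis(R, 1, psi_floor=0.01)
        assert np.all(model.uniquenesses >= 0.01)
        assert "t0" in model.heywood

    def test_invalid_k_rejected(self):
        R = pd.DataFrame(np.eye(4), index=self._traits(4),
                         columns=self._traits(4))
        for k in (0, 4, 7):
            with pytest.raises(ValueError):
                rp.ml_factor_analysis(R, k)


class TestFactorScores:
    def test_single_loading_recovers_trait(self):
        traits = ["t0", "t1", "t2"]
        loadings = pd.DataFrame([[1.0], [0.0], [0.0]], index=traits,
                                columns=["F1"])
        model = rp.types.FactorModel(
            loadings=loadings,
            uniquenesses=pd.Series([0.0, 1.0, 1.0], index=traits),
            variance_explained=np.array([1 / 3]),
            cumulative_variance=np.array([1 / 3]), n_factors=1)
        Z = pd.DataFrame(np.random.default_rng(1).normal(size=(5, 3)),
                         columns=traits)
        R = pd.DataFrame(np.eye(3), index=traits, columns=traits)
        scores = rp.factor_scores(Z, model, R)
        assert scores["F1"].to_numpy() == pytest.approx(
            Z["t0"].to_numpy(), abs=1e-12)
        zero_row = rp.factor_scores(Z * 0.0, model, R)
        assert np.all(zero_row.to_numpy() == 0.0)

    def test_simulated_three_factor_score_recovery(self):
        # factors differ in strength and breadth: equal-strength orthogonal
        # factors are rotationally unidentified in an unrotated ML model
        rng = np.random.default_rng(12)
        n, p, k = 200, 30, 3
        F = rng.normal(size=(n, k))
        lam = np.zeros((p, k))
        off = 0
        for j, (size, s) in enumerate(zip((15, 10, 5), (0.9, 0.8, 0.7))):
            lam[off:off + size, j] = s
            off += size
        X = pd.DataFrame(F @ lam.T + rng.normal(size=(n, p)) * 0.5,
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"t{i}" for i in range(p)])
        fa = rp.FactorAnalysisPipeline(n_factors=3).fit(X)
        cors = np.abs(np.corrcoef(fa.scores_.to_numpy().T, F.T)[:k, k:])
        best = cors.max(axis=1)
        assert np.all(best > 0.9)


class TestPipelineEstimator:
    def test_sklearn_contract_and_determinism(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(40, 12)),
                         index=[f"s{i}" for i in range(40)])
        X.iloc[0, :5] = np.nan           # > 25% missing -> dropped in fit
        fa = rp.FactorAnalysisPipeline(n_factors=2)
        params = fa.get_params()
        assert params["max_missing_fraction"] == 0.25
        fa.set_params(variance_floor=0.05).fit(X)
        assert fa.removed_strains_ == ["s0"]
        assert fa.loadings_.shape == (12, 2)
        # transform on the training matrix reproduces fit scores
        scores = fa.transform(X.drop(index="s0"))
        pd.testing.assert_frame_equal(scores, fa.scores_)
        fa2 = rp.FactorAnalysisPipeline(n_factors=2,
                                        variance_floor=0.05).fit(X)
        pd.testing.assert_frame_equal(fa.loadings_, fa2.loadings_)

    def test_variance_report_floor_flag(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(60, 10)))
        fa = rp.FactorAnalysisPipeline(n_factors=3,
                                       variance_floor=0.013).fit(X)
        rep = fa.variance_report_
        assert np.all(np.diff(rep["cumulative"]) >= -1e-12)
        assert np.all(rep["variance_explained"] >= 0)
        assert rep.loc[rep["variance_explained"] < 0.013,
                       "excluded"].all()

    def test_strain_profiles_subset(self):
        scores = pd.DataFrame(np.zeros((4, 10)),
                              columns=[f"F{i}" for i in range(10)])
        prof = rp.strain_profiles(scores, first_k=8)
        assert prof.shape == (4, 8)
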