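"""Per-trait strain/sex decomposition: GLM tests, variance components,
heritability, effect sizes, FDR q-values, strain means and outlier flags.

The per-trait model is a two-way strain x sex layout::

    y_ijk = mu + strain_i + sex_j + (strain x sex)_ij + e_ijk

tested with non-sequential (Type-III-style) F tests, and decomposed into
variance components by REML (default) or ANOVA expected-mean-squares
estimators.  Heritability is the strain intra-class correlation
``h2 = sigma2_strain / (sigma2_strain + sigma2_error)`` with a large-sample
standard error using Searle's effective per-strain sample size
``n0 = (N - sum(n_i^2)/N) / (s - 1)`` for unbalanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import HeritabilityEstimate, VarianceComponents

__all__ = [
    "GLMTestResult", "fit_strain_sex_glm", "estimate_variance_components",
    "heritability", "partial_omega2", "classify_effect_size",
    "storey_qvalues", "strain_means", "strain_trait_matrix",
    "sex_policy_decision", "flag_univariate_outliers", "effects_table",
]


# ---------------------------------------------------------------------------
# Type-III GLM tests

@dataclass
class GLMTestResult:
    p_strain: float
    p_sex: float
    p_interaction: float
    F_strain: float = float("nan")
    F_sex: float = float("nan")
    F_interaction: float = float("nan")
    degenerate: bool = False


def _sum_coded(labels: np.ndarray, levels: list) -> np.ndarray:
    """Deviation (sum-to-zero) coding: one column per non-reference level."""
    n, L = len(labels), len(levels)
    X = np.zeros((n, L - 1))
    for j, lev in enumerate(levels[:-1]):
        X[labels == lev, j] = 1.0
    X[labels == levels[-1], :] = -1.0
    return X


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_strain_sex_glm(data: pd.DataFrame, trait_id: str) -> GLMTestResult:
    """Marginal (Type-III) F tests for strain, sex and strain-by-sex.

    Each effect is tested by comparing the full sum-coded model against the
    model with that effect's columns removed; p-values come from the exact F
    distribution.  A trait observed in only one sex gets NaN sex/interaction
    tests with the strain test still computed; an all-constant trait is
    flagged degenerate with p = 1 by convention.
    """
    d = data.loc[data["trait"].eq(trait_id) & data["value"].notna()]
    y = d["value"].to_numpy(dtype=float)
    strains = sorted(d["strain"].unique())
    sexes = sorted(d["sex"].unique())
    if len(strains) < 2:
        raise ValueError("need at least two strains")

    one = np.ones((len(d), 1))
    S = _sum_coded(d["strain"].to_numpy(), strains)
    if np.ptp(y) == 0.0:
        return GLMTestResult(1.0, 1.0, 1.0, degenerate=True)

    if len(sexes) < 2:
        rss1, rank1 = _rss(np.hstack([one, S]), y)
        rss0, rank0 = _rss(one, y)
        df1, df2 = rank1 - rank0, len(y) - rank1
        if df2 <= 0 or rss1 <= 1e-12 * rss0:
            return GLMTestResult(1.0, np.nan, np.nan, degenerate=True)
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
        return GLMTestResult(float(stats.f.sf(F, df1, df2)), np.nan, np.nan,
                             F_strain=float(F))

    x_sex = np.where(d["sex"].to_numpy() == sexes[0], 1.0, -1.0)[:, None]
    I = S * x_sex
    blocks = {"strain": S, "sex": x_sex, "interaction": I}
    X_full = np.hstack([one, S, x_sex, I])
    rss_full, rank_full = _rss(X_full, y)
    df2 = len(y) - rank_full

    out: dict[str, tuple[float, float]] = {}
    degenerate = df2 <= 0 or rss_full <= 1e-12 * float(y @ y - len(y) * y.mean() ** 2 + 1e-300)
    for name in blocks:
        Xr = np.hstack([one] + [b for k, b in blocks.items() if k != name])
        rss_red, rank_red = _rss(Xr, y)
        df1 = rank_full - rank_red
        if degenerate or df1 <= 0:
            out[name] = (np.nan, 1.0)
            continue
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
        out[name] = (float(F), float(stats.f.sf(F, df1, df2)))
    return GLMTestResult(
        p_strain=out["strain"][1], p_sex=out["sex"][1],
        p_interaction=out["interaction"][1],
        F_strain=out["strain"][0], F_sex=out["sex"][0],
        F_interaction=out["interaction"][0], degenerate=degenerate)


# ---------------------------------------------------------------------------
# Variance components: ANOVA (EMS) and REML

def _searle_n0(n_i: np.ndarray) -> float:
    N, s = n_i.sum(), len(n_i)
    return float((N - (n_i ** 2).sum() / N) / (s - 1))


def _oneway_anova_vc(y: np.ndarray, strain: np.ndarray) -> tuple[float, float]:
    """Expected-mean-squares estimators for the one-way random model."""
    levels, inv = np.unique(strain, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    means = np.bincount(inv, weights=y) / n_i
    grand = y.mean()
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(((y - means[inv]) ** 2).sum())
    s, N = len(levels), len(y)
    msw = ssw / (N - s) if N > s else 0.0
    msb = ssb / (s - 1)
    n0 = _searle_n0(n_i)
    return (msb - msw) / n0, msw


def _oneway_reml(y: np.ndarray, strain: np.ndarray) -> tuple[float, float]:
    """One-way REML by 1-D profile likelihood over lambda = s2_strain/s2_e.

    Per-strain block structure makes every quantity a sum over strains, so
    the profile is cheap and can be optimized to near machine precision
    (balanced designs then reproduce the ANOVA estimators exactly).
    """
    levels, inv = np.unique(strain, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    sum_i = np.bincount(inv, weights=y)
    yy = float(y @ y)
    N = len(y)

    def _forms(lam: float):
        w = lam / (1.0 + n_i * lam)          # shrinkage per strain block
        # quadratic forms through the per-block Woodbury identity
        xvx = N - float((w * n_i ** 2).sum())
        xvy = float(sum_i.sum() - (w * n_i * sum_i).sum())
        yvy = yy - float((w * sum_i ** 2).sum())
        return xvx, xvy, yvy

    def neg_profile(log_lam: float) -> float:
        lam = np.exp(log_lam)
        xvx, xvy, yvy = _forms(lam)
        logdet = float(np.log1p(n_i * lam).sum())
        ypy = yvy - xvy ** 2 / xvx
        if ypy <= 0:
            return np.inf
        s2e = ypy / (N - 1)
        return 0.5 * (logdet + np.log(xvx) + (N - 1) * (1.0 + np.log(s2e)))

    def score(log_lam: float) -> float:
        # d(neg_profile)/d(log lam), analytic
        lam = np.exp(log_lam)
        xvx, xvy, yvy = _forms(lam)
        dw = 1.0 / (1.0 + n_i * lam) ** 2
        dxvx = -float((dw * n_i ** 2).sum())
        dxvy = -float((dw * n_i * sum_i).sum())
        dyvy = -float((dw * sum_i ** 2).sum())
        ypy = yvy - xvy ** 2 / xvx
        dypy = dyvy - (2 * xvy * dxvy * xvx - xvy ** 2 * dxvx) / xvx ** 2
        d = 0.5 * (float((n_i / (1.0 + n_i * lam)).sum()) + dxvx / xvx
                   + (N - 1) * dypy / ypy)
        return d * lam

    res = optimize.minimize_scalar(neg_profile, bounds=(-30.0, 15.0),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    x = float(res.x)
    # polish to machine precision on the analytic score equation
    lo_, hi_ = x - 0.5, x + 0.5
    try:
        if score(lo_) < 0 < score(hi_):
            x = float(optimize.brentq(score, lo_, hi_, xtol=1e-14,
                                      rtol=1e-15))
    except ValueError:
        pass
    lam = float(np.exp(x))
    w = lam / (1.0 + n_i * lam)
    xvx = N - float((w * n_i ** 2).sum())
    xvy = float(sum_i.sum() - (w * n_i * sum_i).sum())
    yvy = yy - float((w * sum_i ** 2).sum())
    s2e = (yvy - xvy ** 2 / xvx) / (N - 1)
    return lam * s2e, s2e


def _multi_reml(y: np.ndarray, factor_codes: list[np.ndarray],
                ) -> list[float]:
    """REML for several crossed random factors plus error (intercept fixed).

    Profiles the error variance out and optimizes the log variance ratios
    with L-BFGS-B through a Woodbury factorization, so cost scales with the
    total number of random-effect levels rather than the number of animals.
    Returns ``[sigma2_1, ..., sigma2_K, sigma2_e]``.
    """
    N = len(y)
    Zs = []
    for codes in factor_codes:
        _, inv = np.unique(codes, return_inverse=True)
        m = inv.max() + 1
        Z = np.zeros((N, m))
        Z[np.arange(N), inv] = 1.0
        Zs.append(Z)
    Z = np.hstack(Zs)
    groups = np.concatenate([np.full(z.shape[1], k)
                             for k, z in enumerate(Zs)])
    X = np.ones((N, 1))
    ZtZ, Zty, ZtX = Z.T @ Z, Z.T @ y, Z.T @ X
    yty, Xty, XtX = float(y @ y), float(y.sum()), float(N)

    def neg_reml(log_gamma: np.ndarray) -> float:
        gam = np.exp(log_gamma)[groups]
        A = ZtZ + np.diag(1.0 / gam)
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return np.inf
        sa = np.linalg.solve(L, np.column_stack([Zty, ZtX[:, 0]]))
        yvy = yty - float(sa[:, 0] @ sa[:, 0])
        xvy = Xty - float(sa[:, 0] @ sa[:, 1])
        xvx = XtX - float(sa[:, 1] @ sa[:, 1])
        logdet = 2.0 * float(np.log(np.diag(L)).sum()) + float(np.log(gam).sum())
        ypy = yvy - xvy ** 2 / xvx
        if ypy <= 0 or xvx <= 0:
            return np.inf
        s2e = ypy / (N - 1)
        return 0.5 * (logdet + np.log(xvx) + (N - 1) * (1.0 + np.log(s2e)))

    K = len(Zs)
    best = None
    for start in (np.full(K, -2.0), np.full(K, 0.0), np.full(K, -6.0)):
        res = optimize.minimize(neg_reml, start, method="L-BFGS-B",
                                bounds=[(-25.0, 12.0)] * K,
                                options={"ftol": 1e-14, "gtol": 1e-10,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    gam = np.exp(best.x)
    gfull = gam[groups]
    A = ZtZ + np.diag(1.0 / gfull)
    L = np.linalg.cholesky(A)
    sa = np.linalg.solve(L, np.column_stack([Zty, ZtX[:, 0]]))
    yvy = yty - float(sa[:, 0] @ sa[:, 0])
    xvy = Xty - float(sa[:, 0] @ sa[:, 1])
    xvx = XtX - float(sa[:, 1] @ sa[:, 1])
    s2e = (yvy - xvy ** 2 / xvx) / (N - 1)
    return [float(g * s2e) for g in gam] + [float(s2e)]


def _twoway_anova_vc(y: np.ndarray, strain: np.ndarray, sex: np.ndarray,
                     ) -> tuple[float, float, float, float]:
    """EMS estimators for the two-way random model on cell means.

    Exact for balanced data; unbalanced designs use the harmonic mean cell
    size (documented approximation; REML is the default estimator).
    """
    df = pd.DataFrame({"y": y, "strain": strain, "sex": sex})
    cells = df.groupby(["strain", "sex"], observed=True)["y"]
    cell_mean = cells.mean().unstack()      # strains x sexes
    cell_n = cells.size().unstack()
    a, b = cell_mean.shape
    n_h = float(stats.hmean(cell_n.to_numpy().ravel()))
    m = cell_mean.to_numpy()
    mi, mj, mm = m.mean(axis=1), m.mean(axis=0), m.mean()
    msa = n_h * b * float(((mi - mm) ** 2).sum()) / (a - 1)
    msb = n_h * a * float(((mj - mm) ** 2).sum()) / (b - 1)
    msab = n_h * float(((m - mi[:, None] - mj[None, :] + mm) ** 2).sum()) \
        / ((a - 1) * (b - 1))
    within = df["y"] - df.merge(cell_mean.stack().rename("cm"),
                                left_on=["strain", "sex"],
                                right_index=True)["cm"]
    dfe = len(y) - a * b
    mse = float((within ** 2).sum()) / dfe if dfe > 0 else 0.0
    s2_ab = (msab - mse) / n_h
    s2_a = (msa - msab) / (b * n_h)
    s2_b = (msb - msab) / (a * n_h)
    return s2_a, s2_b, s2_ab, mse


def estimate_variance_components(data: pd.DataFrame, trait_id: str,
                                 scope: str = "pooled",
                                 method: str = "reml",
                                 include_sex_terms: bool = True,
                                 ) -> VarianceComponents:
    """Variance components for one trait within a scope.

    ``scope`` is ``"female"``/``"male"`` (one-way random strain model on that
    sex) or ``"pooled"`` (random strain, sex and strain-by-sex components by
    default; set ``include_sex_terms=False`` for the strain-only pooled
    model).  ``method`` is ``"reml"`` (default) or ``"anova"``
    (expected-mean-squares estimators).  Negative estimates are truncated to
    zero and flagged.
    """
    d = data.loc[data["trait"].eq(trait_id) & data["value"].notna()]
    if scope in ("female", "male"):
        d = d[d["sex"].eq("F" if scope == "female" else "M")]
    elif scope != "pooled":
        raise ValueError(f"unknown scope {scope!r}")
    y = d["value"].to_numpy(dtype=float)
    strain = d["strain"].to_numpy()
    if len(np.unique(strain)) < 2:
        raise ValueError("need at least two strains in scope")

    cell = pd.Series(y).groupby([pd.Series(strain), pd.Series(d["sex"].to_numpy())]).transform("mean")
    resid = y - cell.to_numpy()
    skew = float(stats.skew(resid)) if len(y) > 2 else np.nan
    kurt = float(stats.kurtosis(resid)) if len(y) > 3 else np.nan

    sexes = d["sex"].unique()
    two_way = scope == "pooled" and include_sex_terms and len(sexes) == 2
    if np.ptp(y) == 0.0:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, scope=scope,
                                  method=method, skewness=skew, kurtosis=kurt)

    if two_way:
        sex = d["sex"].to_numpy()
        inter = np.char.add(np.char.add(strain.astype(str), ":"),
                            sex.astype(str))
        if method == "anova":
            s2s, s2x, s2i, s2e = _twoway_anova_vc(y, strain, sex)
        elif method == "reml":
            s2s, s2x, s2i, s2e = _multi_reml(y, [strain, sex, inter])
        else:
            raise ValueError(f"unknown method {method!r}")
        raw = {"strain": s2s, "sex": s2x, "interaction": s2i, "error": s2e}
    else:
        if method == "anova":
            s2s, s2e = _oneway_anova_vc(y, strain)
        elif method == "reml":
            s2s, s2e = _oneway_reml(y, strain)
        else:
            raise ValueError(f"unknown method {method!r}")
        raw = {"strain": s2s, "sex": 0.0, "interaction": 0.0, "error": s2e}

    truncated = tuple(k for k, v in raw.items() if v < 0)
    clipped = {k: max(0.0, v) for k, v in raw.items()}
    return VarianceComponents(
        sigma2_strain=clipped["strain"], sigma2_error=clipped["error"],
        sigma2_sex=clipped["sex"], sigma2_interaction=clipped["interaction"],
        scope=scope, method=method, truncated=truncated,
        skewness=skew, kurtosis=kurt)


# ---------------------------------------------------------------------------
# Heritability and effect sizes

def heritability(vc: VarianceComponents, group_sizes: np.ndarray | pd.Series,
                 ) -> HeritabilityEstimate:
    """Strain intra-class correlation h2 = s2_strain / (s2_strain + s2_error).

    The standard error is the classical large-sample intra-class-correlation
    formula ``Var(t) = 2 (1-t)^2 [1 + (n0-1) t]^2 / [n0 (n0-1) (s-1)]`` with
    Searle's ``n0`` adjusting for unbalanced per-strain sample sizes.
    """
    n_i = np.asarray(group_sizes, dtype=float)
    n_i = n_i[n_i > 0]
    s, N = len(n_i), int(n_i.sum())
    if s < 2:
        raise ValueError("need at least two strains")
    n0 = _searle_n0(n_i)
    denom = vc.sigma2_strain + vc.sigma2_error
    if denom <= 0:
        return HeritabilityEstimate(np.nan, np.nan, n0, s, N,
                                    scope=vc.scope, degenerate=True)
    t = float(np.clip(vc.sigma2_strain / denom, 0.0, 1.0))
    var_t = 2.0 * (1.0 - t) ** 2 * (1.0 + (n0 - 1.0) * t) ** 2 \
        / (n0 * (n0 - 1.0) * (s - 1.0))
    return HeritabilityEstimate(t, float(np.sqrt(max(var_t, 0.0))),
                                n0, s, N, scope=vc.scope)


def partial_omega2(vc: VarianceComponents) -> tuple[float, float, float]:
    """Partial omega-squared per effect: sigma2_effect / total variance."""
    total = vc.total()
    if total <= 0:
        return (np.nan, np.nan, np.nan)
    return (vc.sigma2_strain / total, vc.sigma2_sex / total,
            vc.sigma2_interaction / total)


def classify_effect_size(omega2_strain: float) -> str:
    """Large (> 0.30), intermediate ((0.10, 0.30]) or small (<= 0.10)."""
    if not 0.0 <= omega2_strain <= 1.0:
        raise ValueError("omega2 must be in [0, 1]")
    if omega2_strain > 0.30:
        return "large"
    if omega2_strain > 0.10:
        return "intermediate"
    return "small"


# ---------------------------------------------------------------------------
# Storey q-values

def storey_qvalues(pvalues, pi0: float | None = None,
                   lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on a lambda grid as ``#{p > lambda} / (m (1-lambda))``,
    smoothed with a cubic polynomial and evaluated at the largest lambda,
    then clipped to (0, 1].  With ``pi0=1`` the result equals
    Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    if pi0 is None:
        lambdas = np.arange(0.05, 0.96, 0.05) if lambdas is None else lambdas
        pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam))
                          for lam in lambdas])
        if m < 100 or np.all(pi0_l == 0):
            pi0 = 1.0
        else:
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(1.0, pi0)
        if pi0 <= 0:
            pi0 = 1.0 / m
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def expected_false_positives(n_discoveries: int, q: float = 0.05) -> float:
    """Expected number of false positives among discoveries at a q cut.

    Calling every test with q-value below ``q`` significant controls the
    FDR at ``q``, so among ``n_discoveries`` such calls about
    ``q * n_discoveries`` are expected to be false.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    return q * n_discoveries


# ---------------------------------------------------------------------------
# Strain means and policies

def strain_means(data: pd.DataFrame, trait_id: str,
                 policy: str = "pooled-LS") -> pd.Series:
    """Per-strain means for one trait under a sex policy.

    ``"female"``/``"male"``: arithmetic strain mean within that sex.
    ``"pooled-LS"``: least-squares mean, the equal-weight average of the two
    per-sex strain means (missing if either sex is unobserved).
    """
    d = data.loc[data["trait"].eq(trait_id) & data["value"].notna()]
    if policy in ("female", "male"):
        sub = d[d["sex"].eq("F" if policy == "female" else "M")]
        return sub.groupby("strain")["value"].mean().rename(trait_id)
    if policy != "pooled-LS":
        raise ValueError(f"unknown policy {policy!r}")
    by_sex = d.groupby(["strain", "sex"])["value"].mean().unstack()
    for col in ("F", "M"):
        if col not in by_sex.columns:
            by_sex[col] = np.nan
    return ((by_sex["F"] + by_sex["M"]) / 2.0).rename(trait_id)


def strain_trait_matrix(data: pd.DataFrame,
                        policy: str | dict[str, str] = "pooled-LS",
                        ) -> pd.DataFrame:
    """Strain-by-trait matrix of strain means (per-trait policies allowed)."""
    traits = data["trait"].unique()
    cols = {t: strain_means(data, t,
                            policy if isinstance(policy, str)
                            else policy.get(t, "pooled-LS"))
            for t in traits}
    return pd.DataFrame(cols)


def sex_policy_decision(q_sex: float, q_interaction: float,
                        threshold: float = 0.05) -> str:
    """``"by_sex"`` if the sex or interaction q-value clears the threshold.

    A trend toward a sex difference or interaction means the sexes are mapped
    separately; otherwise they are pooled. NaN q-values count as no trend.
    """
    for q in (q_sex, q_interaction):
        if np.isfinite(q) and q < threshold:
            return "by_sex"
    return "pooled"


def flag_univariate_outliers(data: pd.DataFrame, trait_id: str,
                             n_sd: float = 5.0) -> pd.Series:
    """Flag animals whose value deviates > n_sd SD from the trait mean.

    Flags are informational: flagged values are retained in all downstream
    analyses.  Zero-SD traits yield no flags.
    """
    d = data.loc[data["trait"].eq(trait_id) & data["value"].notna()]
    if len(d) < 3:
        raise ValueError("need at least three observations")
    v = d["value"].to_numpy(dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        flags = np.zeros(len(d), dtype=bool)
    else:
        flags = np.abs(v - v.mean()) > n_sd * sd
    return pd.Series(flags, index=d["animal"].to_numpy(), name=trait_id)


# ---------------------------------------------------------------------------
# Per-trait driver

def effects_table(data: pd.DataFrame, traits=None, method: str = "reml",
                  q_threshold: float = 0.05) -> pd.DataFrame:
    """Full per-trait effects summary across the phenotype table.

    For each trait: Type-III p-values, pooled variance components and partial
    omega2, per-scope heritability with SE, effect-size class; then Storey
    q-values across traits for the three effects and the resulting sex
    policy.
    """
    traits = list(data["trait"].unique()) if traits is None else list(traits)
    rows = []
    for t in traits:
        glm = fit_strain_sex_glm(data, t)
        vc = estimate_variance_components(data, t, scope="pooled",
                                          method=method)
        om = partial_omega2(vc)
        d = data.loc[data["trait"].eq(t) & data["value"].notna()]
        row = {
            "trait": t, "p_strain": glm.p_strain, "p_sex": glm.p_sex,
            "p_interaction": glm.p_interaction,
            "omega2_strain": om[0], "omega2_sex": om[1],
            "omega2_interaction": om[2],
            "effect_class": (classify_effect_size(om[0])
                             if np.isfinite(om[0]) else "undefined"),
            "degenerate": glm.degenerate,
        }
        for scope in ("female", "male", "pooled"):
            try:
                vcs = (vc if scope == "pooled" else
                       estimate_variance_components(data, t, scope=scope,
                                                    method=method))
                sub = d if scope == "pooled" else d[
                    d["sex"].eq("F" if scope == "female" else "M")]
                h = heritability(vcs, sub.groupby("strain").size())
                row[f"h2_{scope}"], row[f"h2_{scope}_se"] = h.h2, h.se
            except ValueError:
                row[f"h2_{scope}"] = row[f"h2_{scope}_se"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("trait")
    for eff in ("strain", "sex", "interaction"):
        p = table[f"p_{eff}"].to_numpy(dtype=float)
        q = np.full_like(p, np.nan)
        ok = np.isfinite(p)
        if ok.any():
            q[ok] = storey_qvalues(p[ok])
        table[f"q_{eff}"] = q
    table["sex_policy"] = [
        sex_policy_decision(qs, qi, threshold=q_threshold)
        for qs, qi in zip(table["q_sex"], table["q_interaction"])]
    return table
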