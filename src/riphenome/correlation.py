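"""Genetic correlation of strain means.

In an RI panel the correlation of strain means between two traits -- or
between a trait and transcript abundance -- reflects shared genetic
influence.  Correlations are Pearson by default (Spearman available), with
two-sided p-values from the t transform on n - 2 degrees of freedom, and
expression correlate lists use the conventional raw p < 0.001 cut with no
multiplicity correction at this stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix

__all__ = ["correlate_strain_means", "expression_correlates"]


def correlate_strain_means(x: pd.Series, y: pd.Series,
                           method: str = "pearson",
                           ) -> tuple[float, float, int]:
    """Correlation of two strain-indexed vectors on their shared strains.

    Returns ``(r, p, n)``.  Requires at least three shared strains after the
    inner join; a zero-variance vector yields ``(nan, nan, n)``.
    """
    joined = pd.concat([x, y], axis=1, join="inner", keys=["x", "y"]).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least three shared strains")
    xv, yv = joined["x"].to_numpy(float), joined["y"].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return (np.nan, np.nan, n)
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return (float(r), float(p), n)


def expression_correlates(trait_means: pd.Series, expr: ExpressionMatrix,
                          p_threshold: float = 0.001,
                          method: str = "pearson",
                          ) -> pd.DataFrame:
    """Genes whose expression correlates with a trait at p below threshold.

    Correlates every probe against the trait strain means over shared
    strains, keeps probes passing the p-value threshold and collapses probes
    to genes keeping the max-|r| probe per gene.  Returns a DataFrame with
    columns ``gene, probe, r, p, n`` sorted by |r| descending.
    """
    cols = ["gene", "probe", "r", "p", "n"]
    if expr.values.shape[0] == 0:
        return pd.DataFrame(columns=cols)
    shared = [s for s in expr.values.columns
              if s in trait_means.index and np.isfinite(trait_means[s])]
    if len(shared) == 0:
        raise ValueError("no shared strains between trait and expression")
    if len(shared) < 3:
        raise ValueError("need at least three shared strains")
    if len(shared) < 10:
        import warnings
        warnings.warn(f"only {len(shared)} shared strains; "
                      "correlations will be unstable")

    y = trait_means.loc[shared].to_numpy(float)
    X = expr.values[shared].to_numpy(float)
    if method == "spearman":
        y = stats.rankdata(y)
        X = np.apply_along_axis(stats.rankdata, 1, X)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    n = len(shared)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((yc ** 2).sum())
    xnorm = np.sqrt((Xc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (xnorm * ynorm)
    r = np.where(np.isfinite(r), r, np.nan)
    rr = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1.0 - rr ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    hits = pd.DataFrame({
        "gene": expr.probe_gene.to_numpy(),
        "probe": expr.values.index.to_numpy(),
        "r": r, "p": p, "n": n,
    })
    hits = hits[np.isfinite(hits["r"]) & (hits["p"] < p_threshold)]
    hits = hits.reindex(hits["r"].abs().sort_values(ascending=False).index)
    hits = hits.drop_duplicates("gene", keep="first")
    return hits.reset_index(drop=True)[cols]
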