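"""Nested sub-population contrasts.

Strains in an expanding RI panel fall into sub-populations (e.g. the original
Taylor lines versus the recent expansion) that differ at a small set of
private loci.  Global phenotypic differences between sub-populations are
tested with the nested model ``y = mu + subpop + strain(subpop) + e`` using
the alternate F ratio ``F = MS_subpop / MS_strain(subpop)``: individual mice
are replicates within strain, so strain -- not mouse -- is the error stratum,
with degrees of freedom (g - 1, s - g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["NestedTestResult", "nested_subpop_test"]


@dataclass
class NestedTestResult:
    trait_id: str
    F: float
    df_num: int
    df_den: int
    p: float
    group_means: dict[str, float]
    degenerate: bool = False


def nested_subpop_test(data: pd.DataFrame, trait_id: str,
                       subpop_labels: Mapping[str, str] | pd.Series,
                       weighted: bool = True) -> NestedTestResult:
    """Alternate F test of sub-population differences on strain means.

    Sums of squares are computed on strain means weighted by per-strain
    animal counts (Henderson method I analogue); set ``weighted=False`` for
    unweighted strain means.  With zero between-strain variance within groups
    the ratio is undefined and the result is flagged degenerate (unless the
    group effect is also zero, in which case F = 0, p = 1).
    """
    labels = pd.Series(dict(subpop_labels)) \
        if not isinstance(subpop_labels, pd.Series) else subpop_labels
    d = data.loc[data["trait"].eq(trait_id) & data["value"].notna()].copy()
    d["group"] = d["strain"].map(labels)
    if d["group"].isna().any():
        missing = sorted(d.loc[d["group"].isna(), "strain"].unique())
        raise ValueError(f"strains without sub-population label: {missing}")

    per_strain = d.groupby(["group", "strain"])["value"].agg(["mean", "size"])
    groups = per_strain.index.get_level_values("group")
    g = groups.nunique()
    s = len(per_strain)
    if g < 2:
        raise ValueError("need at least two sub-populations")
    if (per_strain.groupby(level="group").size() < 2).any():
        raise ValueError("each sub-population needs at least two strains")

    m = per_strain["mean"].to_numpy()
    w = per_strain["size"].to_numpy(dtype=float) if weighted \
        else np.ones(s)
    wsum = pd.Series(w, index=per_strain.index).groupby(level="group")
    group_mean = (pd.Series(w * m, index=per_strain.index)
                  .groupby(level="group").sum() / wsum.sum())
    grand = float((w * m).sum() / w.sum())

    gm = group_mean.reindex(groups).to_numpy()
    Ng = wsum.sum().to_numpy()
    ss_sub = float((Ng * (group_mean.to_numpy() - grand) ** 2).sum())
    ss_strain = float((w * (m - gm) ** 2).sum())
    df_num, df_den = g - 1, s - g
    ms_sub = ss_sub / df_num
    ms_strain = ss_strain / df_den

    scale = float((w * m ** 2).sum()) + 1e-300
    means_out = {k: float(v) for k, v in group_mean.items()}
    if ms_strain <= 1e-12 * scale:
        if ms_sub <= 1e-12 * scale:
            return NestedTestResult(trait_id, 0.0, df_num, df_den, 1.0,
                                    means_out)
        return NestedTestResult(trait_id, np.nan, df_num, df_den, np.nan,
                                means_out, degenerate=True)
    F = ms_sub / ms_strain
    return NestedTestResult(trait_id, float(F), df_num, df_den,
                            float(stats.f.sf(F, df_num, df_den)), means_out)
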