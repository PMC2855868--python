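"""Shared data containers.

Conventions used throughout the package:

* A *marker map* is a :class:`pandas.DataFrame` with columns
  ``marker, chrom, cM, Mb`` (one row per marker, cM/Mb non-decreasing within
  a chromosome).
* *Individual phenotypes* are a long-format :class:`pandas.DataFrame` with
  columns ``animal, strain, sex, battery, trait, value`` where ``sex`` is
  ``"M"``/``"F"`` and ``value`` may be NaN (missing).
* A *strain-by-trait matrix* is a wide :class:`pandas.DataFrame` indexed by
  strain with one column per trait.
* A *gene annotation table* is a :class:`pandas.DataFrame` with columns
  ``gene, chrom, start_Mb, end_Mb`` (half-open megabase intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPE_CODES = frozenset("BDHU")

#: numeric dosage of the D allele for each genotype code (U = unknown)
DOSAGE = {"B": 0.0, "D": 1.0, "H": 0.5, "U": np.nan}

PHENOTYPE_COLUMNS = ["animal", "strain", "sex", "battery", "trait", "value"]


@dataclass
class GenotypeMatrix:
    """RI panel genotypes: strains x markers call matrix plus genetic map.

    Parameters
    ----------
    calls : DataFrame
        Strain-indexed matrix, one column per marker, entries in ``B, D, H, U``.
    marker_map : DataFrame
        Columns ``marker, chrom, cM, Mb``, ordered to match ``calls`` columns.
    subpopulation : Series
        Sub-population label per strain (e.g. ``"TaylorI"`` / ``"Recent"``).
    """

    calls: pd.DataFrame
    marker_map: pd.DataFrame
    subpopulation: pd.Series

    def __post_init__(self) -> None:
        self.marker_map = self.marker_map.reset_index(drop=True)
        if list(self.calls.columns) != list(self.marker_map["marker"]):
            raise ValueError("calls columns must match marker_map order")
        if not self.subpopulation.index.equals(self.calls.index):
            self.subpopulation = self.subpopulation.reindex(self.calls.index)
        bad = set(np.unique(self.calls.to_numpy())) - GENOTYPE_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if self.marker_map["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            if (np.diff(grp["cM"].to_numpy()) < 0).any():
                raise ValueError("cM positions must be non-decreasing per chromosome")
            if (np.diff(grp["Mb"].to_numpy()) < 0).any():
                raise ValueError("Mb positions must be non-decreasing per chromosome")

    @property
    def strains(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def dosage(self) -> pd.DataFrame:
        """Numeric D-allele dosage matrix (B=0, D=1, H=0.5, U=NaN)."""
        arr = self.calls.to_numpy()
        num = np.select([arr == "B", arr == "D", arr == "H"],
                        [0.0, 1.0, 0.5], default=np.nan)
        return pd.DataFrame(num, index=self.calls.index,
                            columns=self.calls.columns)


@dataclass
class ExpressionMatrix:
    """Probe-level expression: probes x strains values plus probe->gene map."""

    values: pd.DataFrame          # probes x strains
    probe_gene: pd.Series         # index probe, value gene id
    tissue: str = "synthetic"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        self.probe_gene = self.probe_gene.reindex(self.values.index)


@dataclass
class VarianceComponents:
    """Variance decomposition for one trait (trait units squared).

    Negative raw estimates are truncated to zero with ``truncated`` recording
    which components were clipped. ``skewness``/``kurtosis`` are residual-scale
    normality diagnostics (REML components can be biased under non-normality).
    """

    sigma2_strain: float
    sigma2_error: float
    sigma2_sex: float = 0.0
    sigma2_interaction: float = 0.0
    scope: str = "pooled"
    method: str = "reml"
    truncated: tuple[str, ...] = ()
    skewness: float = float("nan")
    kurtosis: float = float("nan")

    def total(self) -> float:
        return (self.sigma2_strain + self.sigma2_sex
                + self.sigma2_interaction + self.sigma2_error)


@dataclass
class HeritabilityEstimate:
    """Strain intra-class correlation with large-sample standard error."""

    h2: float
    se: float
    n0: float           # Searle effective per-strain sample size
    s: int              # number of strains
    N: int              # total animals
    scope: str = "pooled"
    degenerate: bool = False


@dataclass
class FactorModel:
    """Unrotated maximum-likelihood factor model on the correlation scale."""

    loadings: pd.DataFrame          # traits x k
    uniquenesses: pd.Series         # per trait
    variance_explained: np.ndarray  # per factor, fraction of total variance
    cumulative_variance: np.ndarray
    n_factors: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    heywood: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return self.n_factors


def validate_phenotypes(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format phenotype table contract and return it."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    bad_sex = set(data["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex must be M or F, got {sorted(bad_sex)}")
    if data.duplicated(["animal", "trait"]).any():
        raise ValueError("duplicate (animal, trait) records")
    return data
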