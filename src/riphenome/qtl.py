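"""Haley-Knott QTL mapping on strain means.

Single-QTL genome scans regress strain means on the expected D-allele dosage
at typed markers and at pseudomarkers on a cM grid, with
``LOD = (n/2) log10(RSS0 / RSS1)``.  Genome-wide thresholds come from
permuting strain means against genotype rows: the significant and suggestive
criteria are the genome-wide adjusted P < 0.05 and P < 0.63 quantiles of the
null max-LOD distribution (0.63 = 1 - 1/e, one expected false positive per
scan).  Support intervals use the one-LOD drop-off with linear
interpolation.

Between markers the expected dosage conditions on the two flanking RI
genotypes through the Markov transition probabilities of the inbred RI
chromosome, with recombination fractions expanded by ``R = 4r/(1+6r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import haldane_r, ri_expansion
from .types import GenotypeMatrix

__all__ = [
    "QTLPeak", "QTLScanResult", "ri_expected_dosage", "hk_scan",
    "permutation_thresholds", "one_lod_interval", "find_peaks",
    "positional_candidates", "marker_effect_by_group",
]


def genomewide_p_for_expected_false_positives(k: float = 1.0) -> float:
    """Genome-wide adjusted P yielding ``k`` expected false QTL per scan.

    Treating genome-wide false positives as Poisson with mean ``k``, the
    probability of at least one is ``1 - exp(-k)``; ``k = 1`` gives the
    conventional suggestive criterion (~0.63), while the significant
    criterion fixes the probability itself at 0.05.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    return 1.0 - float(np.exp(-k))


@dataclass
class QTLPeak:
    chrom: str
    pos_cM: float
    pos_Mb: float
    lod: float
    classification: str                    # "significant" or "suggestive"
    support_cM: tuple[float, float]
    support_Mb: tuple[float, float]
    co_peaks_cM: tuple[float, ...] = ()


@dataclass
class QTLScanResult:
    trait_id: str
    loci: pd.DataFrame        # columns: locus, chrom, cM, Mb, lod, typed
    n_strains: int
    strains: tuple[str, ...] = ()
    suggestive_lod: float | None = None
    significant_lod: float | None = None
    n_permutations: int = 0
    peaks: list[QTLPeak] = field(default_factory=list)

    def max_lod(self) -> float:
        return float(self.loci["lod"].max())


def ri_expected_dosage(flank_left, flank_right, r1: float, r2: float):
    """Expected D dosage at a pseudomarker given flanking RI genotypes.

    ``flank_left``/``flank_right`` are D dosages in [0, 1] (0 = B, 1 = D,
    0.5 = heterozygous); ``r1``/``r2`` are meiotic recombination fractions to
    the left and right flank, expanded internally to RI scale.  The RI
    chromosome is Markov, so
    ``P(D | L, R) = t1(L,D) t2(D,R) / sum_x t1(L,x) t2(x,R)``.
    """
    gl = np.asarray(flank_left, dtype=float)
    gr = np.asarray(flank_right, dtype=float)
    if not (0.0 <= r1 <= 0.5 and 0.0 <= r2 <= 0.5):
        raise ValueError("recombination fractions must be in [0, 0.5]")
    R1, R2 = float(ri_expansion(r1)), float(ri_expansion(r2))
    p1 = gl * (1.0 - R1) + (1.0 - gl) * R1      # P(pseudo = D | left)
    q1 = gr * (1.0 - R2) + (1.0 - gr) * R2      # P(right | pseudo = D)
    p0 = gl * R1 + (1.0 - gl) * (1.0 - R1)
    q0 = gr * R2 + (1.0 - gr) * (1.0 - R2)
    denom = p1 * q1 + p0 * q0
    if np.any(denom == 0):
        raise ValueError("inconsistent flanking genotypes at r = 0")
    return p1 * q1 / denom


def _scan_design(genotypes: GenotypeMatrix, step_cM: float | None,
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Locus table (typed markers + grid pseudomarkers) and dosage matrix."""
    dosage = genotypes.dosage()
    mmap = genotypes.marker_map
    loci_rows, cols = [], []
    for chrom, grp in mmap.groupby("chrom", sort=False):
        cm = grp["cM"].to_numpy()
        mb = grp["Mb"].to_numpy()
        names = grp["marker"].to_numpy()
        typed = dosage[names].to_numpy()
        grid = (np.arange(cm[0], cm[-1] + 1e-9, step_cM)
                if step_cM else np.empty(0))
        grid = grid[~np.isin(np.round(grid, 9), np.round(cm, 9))]
        entries = [(float(cm[k]), k) for k in range(len(cm))]
        entries += [(float(pos), None) for pos in grid]
        entries.sort(key=lambda t: (t[0], t[1] is None, t[1]))
        for pos, k in entries:
            if k is not None:
                loci_rows.append((names[k], chrom, pos, float(mb[k]), True))
                cols.append(typed[:, k])
            else:
                j = min(max(int(np.searchsorted(cm, pos, side="right")) - 1,
                            0), len(cm) - 2)
                r1 = float(haldane_r(pos - cm[j]))
                r2 = float(haldane_r(cm[j + 1] - pos))
                cols.append(ri_expected_dosage(typed[:, j], typed[:, j + 1],
                                               r1, r2))
                loci_rows.append((f"c{chrom}@{pos:.2f}", chrom, pos,
                                  float(np.interp(pos, cm, mb)), False))
    loci = pd.DataFrame(loci_rows,
                        columns=["locus", "chrom", "cM", "Mb", "typed"])
    return loci, np.column_stack(cols)


def _lod_matrix(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """LOD per column of X for each column of y (both 2-D, rows = strains)."""
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    xc = X - X.mean(axis=0)
    ynorm = np.sqrt((yc ** 2).sum(axis=0))
    xnorm = np.sqrt((xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / np.outer(xnorm, ynorm)
    r = np.nan_to_num(r)
    r2 = np.clip(r ** 2, 0.0, 1.0 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - r2)


def hk_scan(y: pd.Series, genotypes: GenotypeMatrix,
            step_cM: float | None = 1.0,
            trait_id: str | None = None) -> QTLScanResult:
    """Haley-Knott genome scan of one strain-mean vector.

    Strains are inner-joined between ``y`` and the genotypes, dropping
    missing entries (complete-case).  ``step_cM`` adds pseudomarkers on that
    grid; ``None`` scans typed markers only.  Fewer than 10 strains raises a
    warning but the scan still runs.
    """
    shared = [s for s in genotypes.strains
              if s in y.index and np.isfinite(y.get(s, np.nan))]
    if len(shared) < 3:
        raise ValueError("need at least three shared strains")
    if len(shared) < 10:
        import warnings
        warnings.warn(f"only {len(shared)} strains in scan; power is low")
    sub = GenotypeMatrix(calls=genotypes.calls.loc[shared],
                         marker_map=genotypes.marker_map,
                         subpopulation=genotypes.subpopulation.loc[shared])
    loci, X = _scan_design(sub, step_cM)
    yv = y.loc[shared].to_numpy(dtype=float)[:, None]
    loci = loci.copy()
    loci["lod"] = _lod_matrix(yv, X)[:, 0]
    return QTLScanResult(trait_id=trait_id or str(y.name), loci=loci,
                         n_strains=len(shared), strains=tuple(shared))


def permutation_thresholds(y: pd.Series, genotypes: GenotypeMatrix,
                           n_perm: int = 1000, seed: int = 0,
                           step_cM: float | None = None,
                           ) -> tuple[float, float]:
    """Genome-wide suggestive/significant LOD thresholds by permutation.

    Strain means are permuted against genotype rows (preserving the marker
    correlation structure) and the genome-wide max LOD recorded per
    permutation.  Returns the 37th percentile (suggestive, genome-wide
    P < 0.63) and 95th percentile (significant, P < 0.05).  By default the
    null scans run on typed markers only; pass ``step_cM`` to match a
    pseudomarker grid.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    shared = [s for s in genotypes.strains
              if s in y.index and np.isfinite(y.get(s, np.nan))]
    sub = GenotypeMatrix(calls=genotypes.calls.loc[shared],
                         marker_map=genotypes.marker_map,
                         subpopulation=genotypes.subpopulation.loc[shared])
    _, X = _scan_design(sub, step_cM)
    rng = np.random.default_rng(seed)
    yv = y.loc[shared].to_numpy(dtype=float)
    perms = np.column_stack([rng.permutation(yv) for _ in range(n_perm)])
    max_lod = _lod_matrix(perms, X).max(axis=0)
    suggestive = float(np.quantile(max_lod, 1.0 - 0.63))
    significant = float(np.quantile(max_lod, 1.0 - 0.05))
    return suggestive, significant


def one_lod_interval(positions: np.ndarray, lods: np.ndarray,
                     peak_index: int, drop: float = 1.0,
                     ) -> tuple[float, float]:
    """Support interval: positions where LOD first falls to peak - drop.

    Crossing points are linearly interpolated between grid points; if the
    LOD never drops on a side the interval is truncated at the chromosome
    end.  Flat-topped peaks extend to the outermost grid point of the top
    before the drop-off applies (handled naturally by the walk).
    """
    positions = np.asarray(positions, dtype=float)
    lods = np.asarray(lods, dtype=float)
    target = lods[peak_index] - drop
    lo = positions[0]
    for i in range(peak_index, 0, -1):
        if lods[i - 1] < target:
            f = (lods[i] - target) / (lods[i] - lods[i - 1])
            lo = positions[i] + f * (positions[i - 1] - positions[i])
            break
    hi = positions[-1]
    for i in range(peak_index, len(lods) - 1):
        if lods[i + 1] < target:
            f = (lods[i] - target) / (lods[i] - lods[i + 1])
            hi = positions[i] + f * (positions[i + 1] - positions[i])
            break
    return float(lo), float(hi)


def find_peaks(scan: QTLScanResult, suggestive: float, significant: float,
               ) -> list[QTLPeak]:
    """One peak per chromosome clearing the suggestive threshold.

    The leftmost position of a tied maximum is reported as the peak with all
    co-peaks listed; classification is against the two thresholds and the
    one-LOD support interval is attached in both cM and Mb.
    """
    if suggestive > significant:
        raise ValueError("suggestive threshold must not exceed significant")
    peaks = []
    for chrom, grp in scan.loci.groupby("chrom", sort=False):
        lods = grp["lod"].to_numpy()
        cm = grp["cM"].to_numpy()
        mb = grp["Mb"].to_numpy()
        top = lods.max()
        if top < suggestive:
            continue
        idx = int(np.argmax(lods))          # leftmost on exact ties
        lo, hi = one_lod_interval(cm, lods, idx)
        mb_lo = float(np.interp(lo, cm, mb))
        mb_hi = float(np.interp(hi, cm, mb))
        peaks.append(QTLPeak(
            chrom=chrom, pos_cM=float(cm[idx]), pos_Mb=float(mb[idx]),
            lod=float(top),
            classification=("significant" if top >= significant
                            else "suggestive"),
            support_cM=(lo, hi), support_Mb=(mb_lo, mb_hi),
            co_peaks_cM=tuple(float(c) for c in cm[lods == top])))
    return peaks


def positional_candidates(peak: QTLPeak, annotation: pd.DataFrame,
                          ) -> list[str]:
    """Genes whose half-open [start, end) Mb span overlaps the support
    interval (any overlap counts)."""
    on_chr = annotation[annotation["chrom"].astype(str) == str(peak.chrom)]
    if len(on_chr) == 0:
        import warnings
        warnings.warn(f"no annotation for chromosome {peak.chrom}")
        return []
    lo, hi = peak.support_Mb
    hit = (on_chr["start_Mb"] <= hi) & (on_chr["end_Mb"] > lo)
    return on_chr.loc[hit, "gene"].tolist()


def marker_effect_by_group(y: pd.Series, genotypes: GenotypeMatrix,
                           marker: str,
                           grouping: pd.Series | None = None) -> pd.DataFrame:
    """Mean strain phenotype by allele within each strain group.

    With the default grouping (the panel's sub-population labels) this is the
    group-conditional effect plot used to detect allele-effect sign flips
    between sub-populations.  Empty group-allele cells are NaN.
    """
    if marker not in genotypes.calls.columns:
        raise ValueError(f"unknown marker {marker!r}")
    grouping = genotypes.subpopulation if grouping is None else grouping
    shared = [s for s in genotypes.strains
              if s in y.index and np.isfinite(y.get(s, np.nan))]
    df = pd.DataFrame({
        "y": y.loc[shared],
        "allele": genotypes.calls.loc[shared, marker],
        "group": grouping.loc[shared],
    })
    table = df.groupby(["group", "allele"], observed=True)["y"].mean().unstack()
    return table.reindex(columns=[a for a in ("B", "D", "H")
                                  if a in table.columns or a in ("B", "D")])
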