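"""End-to-end pipeline driver on a synthetic panel.

Executes the analysis graph: simulate -> per-trait effects -> strain means
-> sub-population tests -> QTL scans with permutation thresholds ->
expression correlates -> factor pipeline -> factor QTL -> multivariate
outliers -> bipartite integration -> gene-set enrichment.  Every output file
carries a header comment with the configuration hash and seed, and a
manifest records seeds, versions and every threshold used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as rio
from .bipartite import (build_bipartite, connectivity_ranking,
                        hypergeometric_enrichment, top_slice)
from .correlation import expression_correlates
from .effects import effects_table, storey_qvalues, strain_trait_matrix
from .factors import FactorAnalysisPipeline
from .outliers import mahalanobis_outliers
from .qtl import find_peaks, hk_scan, permutation_thresholds, \
    positional_candidates
from .simulate import (SimulationConfig, make_gene_annotation, make_genesets,
                       simulate_expression, simulate_genotypes,
                       simulate_phenotypes)
from .subpop import nested_subpop_test

log = logging.getLogger("riphenome")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a full synthetic-panel run.

    The thresholds mirror the analysis conventions: q < 0.05 for FDR calls,
    correlate p < 0.001, 1000 permutations with genome-wide suggestive /
    significant criteria P < 0.63 / 0.05, a 25% strain-missingness filter,
    a 1.3% factor variance floor, outlier alpha 0.05 and top 5%/10%
    connectivity slices.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    q_threshold: float = 0.05
    correlate_p: float = 0.001
    n_permutations: int = 1000
    step_cM: float | None = 1.0
    max_missing_fraction: float = 0.25
    variance_floor: float = 0.013
    outlier_alpha: float = 0.05
    top_fractions: tuple[float, ...] = (0.05, 0.10)
    n_qtl_traits: int = 3
    n_factor_qtl: int = 3
    n_outlier_traits: int = 4
    vc_method: str = "reml"
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing TSV/JSON outputs plus a manifest.

    Returns the manifest dictionary.  A stage failure halts the run with the
    stage name in the exception; outputs of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = {"config_hash": config.digest(), "seed": config.seed,
            "version": __version__}
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": _as_jsonable(config),
                      "config_hash": config.digest(),
                      "stages": {}, "started": time.strftime("%Y-%m-%d")}
    stage = "simulate"
    try:
        sim = config.simulation
        genotypes = simulate_genotypes(sim)
        phenotypes = simulate_phenotypes(genotypes, sim)
        annotation = make_gene_annotation(genotypes.marker_map)
        genesets = make_genesets(annotation, seed=sim.seed)
        expr = simulate_expression(genotypes, sim, annotation=annotation)
        rio.write_geno(genotypes, outdir / "panel.geno", header=head)
        rio.write_traits(phenotypes, outdir / "traits.csv", header=head)
        rio.write_bed(annotation, outdir / "genes.bed", header=head)
        rio.write_gmt(genesets, outdir / "genesets.gmt")
        rio.write_expression(expr, outdir / "expression.tsv", header=head)
        manifest["stages"][stage] = {
            "n_strains": len(genotypes.strains),
            "n_markers": genotypes.n_markers,
            "n_traits": len(sim.traits), "n_animals":
                int(phenotypes["animal"].nunique())}

        stage = "effects"
        eff = effects_table(phenotypes, method=config.vc_method,
                            q_threshold=config.q_threshold)
        _write_tsv(eff, outdir / "effects.tsv", head)
        manifest["stages"][stage] = {
            "n_traits": len(eff),
            "by_sex": int((eff["sex_policy"] == "by_sex").sum())}

        stage = "strain_means"
        policies = {t: ("pooled-LS" if pol == "pooled" else "female")
                    for t, pol in eff["sex_policy"].items()}
        means = strain_trait_matrix(phenotypes, policies)
        rio.write_strain_matrix(means, outdir / "strain_means.csv", head)
        manifest["stages"][stage] = {"shape": list(means.shape)}

        stage = "subpop"
        rows = []
        for t in eff.index:
            r = nested_subpop_test(phenotypes, t, genotypes.subpopulation)
            rows.append({"trait": t, "F": r.F, "df_num": r.df_num,
                         "df_den": r.df_den, "p": r.p, **{
                             f"mean_{g}": m for g, m in r.group_means.items()}})
        sp = pd.DataFrame(rows).set_index("trait")
        ok = np.isfinite(sp["p"].to_numpy(dtype=float))
        q = np.full(len(sp), np.nan)
        if ok.any():
            q[ok] = storey_qvalues(sp["p"].to_numpy(dtype=float)[ok])
        sp["q"] = q
        _write_tsv(sp, outdir / "subpop.tsv", head)
        manifest["stages"][stage] = {
            "significant": int((sp["q"] < config.q_threshold).sum())}

        stage = "qtl"
        mapped = (eff.sort_values("omega2_strain", ascending=False)
                  .head(config.n_qtl_traits).index.tolist())
        candidate_lists: dict[str, list[str]] = {}
        qtl_rows = []
        for t in mapped:
            y = means[t].dropna()
            scan = hk_scan(y, genotypes, step_cM=config.step_cM, trait_id=t)
            if config.n_permutations > 0:
                sug, sig = permutation_thresholds(
                    y, genotypes, n_perm=config.n_permutations,
                    seed=config.seed + zlib.crc32(t.encode()) % 10000)
                peaks = find_peaks(scan, sug, sig)
                scan.suggestive_lod, scan.significant_lod = sug, sig
                scan.peaks = peaks
                for pk in peaks:
                    genes = positional_candidates(pk, annotation)
                    candidate_lists[f"qtl:{t}:chr{pk.chrom}"] = genes
                    qtl_rows.append({
                        "trait": t, "chrom": pk.chrom, "cM": pk.pos_cM,
                        "Mb": pk.pos_Mb, "lod": pk.lod,
                        "class": pk.classification,
                        "ci_Mb_lo": pk.support_Mb[0],
                        "ci_Mb_hi": pk.support_Mb[1],
                        "n_candidates": len(genes),
                        "suggestive": sug, "significant": sig})
            else:
                log.warning("permutations = 0: thresholds and candidate "
                            "extraction disabled for %s", t)
            _write_tsv(scan.loci.set_index("locus"),
                       outdir / f"scan_{t}.tsv", head)
        peaks_df = pd.DataFrame(qtl_rows)
        _write_tsv(peaks_df.set_index("trait") if len(peaks_df) else peaks_df,
                   outdir / "qtl_peaks.tsv", head)
        manifest["stages"][stage] = {"traits": mapped,
                                     "n_peaks": len(qtl_rows),
                                     "n_permutations": config.n_permutations}

        stage = "expression_correlates"
        for t in mapped:
            hits = expression_correlates(means[t].dropna(), expr,
                                         p_threshold=config.correlate_p)
            if len(hits):
                candidate_lists[f"expr:{t}:{expr.tissue}"] = \
                    hits["gene"].tolist()
            _write_tsv(hits.set_index("gene") if len(hits) else hits,
                       outdir / f"correlates_{t}.tsv", head)
        manifest["stages"][stage] = {"n_lists": len(candidate_lists)}

        stage = "factors"
        fa = FactorAnalysisPipeline(
            max_missing_fraction=config.max_missing_fraction,
            variance_floor=config.variance_floor,
            random_state=config.seed)
        fa.fit(means.dropna(axis=1, how="all"))
        _write_tsv(fa.loadings_, outdir / "factor_loadings.tsv", head)
        _write_tsv(fa.scores_, outdir / "factor_scores.tsv", head)
        _write_tsv(fa.variance_report_, outdir / "factor_variance.tsv", head)
        (outdir / "factor_report.json").write_text(json.dumps({
            "removed_strains": fa.removed_strains_,
            "shrinkage": fa.shrinkage_, "n_factors": fa.n_factors_,
            "criteria": fa.n_factor_criteria_, **head}, indent=2))
        manifest["stages"][stage] = {
            "n_factors": fa.n_factors_, "shrinkage": fa.shrinkage_,
            "removed_strains": len(fa.removed_strains_)}

        stage = "factor_qtl"
        fq_rows = []
        for f in fa.scores_.columns[:config.n_factor_qtl]:
            scan = hk_scan(fa.scores_[f], genotypes, step_cM=config.step_cM,
                           trait_id=f)
            if config.n_permutations > 0:
                sug, sig = permutation_thresholds(
                    fa.scores_[f], genotypes,
                    n_perm=config.n_permutations,
                    seed=config.seed + 7000 + int(f[1:]))
                for pk in find_peaks(scan, sug, sig):
                    fq_rows.append({"factor": f, "chrom": pk.chrom,
                                    "cM": pk.pos_cM, "lod": pk.lod,
                                    "class": pk.classification})
        fq = pd.DataFrame(fq_rows)
        _write_tsv(fq.set_index("factor") if len(fq) else fq,
                   outdir / "factor_qtl.tsv", head)
        manifest["stages"][stage] = {"n_peaks": len(fq_rows)}

        stage = "outliers"
        otraits = [c for c in means.columns
                   if means[c].notna().all()][:config.n_outlier_traits]
        if len(otraits) >= 2:
            rep = mahalanobis_outliers(means[otraits],
                                       alpha=config.outlier_alpha)
            _write_tsv(rep, outdir / "outliers.tsv", head)
            manifest["stages"][stage] = {
                "traits": otraits, "flagged": int(rep["flagged"].sum())}
        else:
            manifest["stages"][stage] = {"skipped": "too few complete traits"}

        stage = "integration"
        if candidate_lists:
            G = build_bipartite(candidate_lists)
            ranking = connectivity_ranking(G)
            _write_tsv(ranking.set_index("gene"),
                       outdir / "gene_ranking.tsv", head)
            universe = annotation["gene"].tolist()
            for frac in config.top_fractions:
                sl = top_slice(ranking, frac)
                enr = hypergeometric_enrichment(sl, genesets, universe)
                _write_tsv(enr, outdir / f"enrichment_top{int(frac * 100)}.tsv",
                           head)
            manifest["stages"][stage] = {
                "n_genes": len(ranking), "n_lists": len(candidate_lists)}
        else:
            manifest["stages"][stage] = {"skipped": "no candidate lists"}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_tsv(df: pd.DataFrame, path: Path, header: dict) -> None:
    with Path(path).open("w") as fh:
        for k, v in header.items():
            fh.write(f"#{k}: {v}\n")
        df.to_csv(fh, sep="\t")
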