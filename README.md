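# riphenome

Quantitative-genetic analysis of recombinant-inbred (RI) phenome panels.

Genetic reference populations such as the BXD RI strains (inbred mosaics of
C57BL/6J "B" and DBA/2J "D" genomes) let phenotypes accumulate across
laboratories and years against a fixed set of genotypes, so traits can be
decomposed, mapped and correlated cumulatively. `riphenome` implements the
full analysis path such a phenome survey needs:

* **Per-trait decomposition** — strain, sex and strain×sex effects by
  Type-III F tests; variance components by REML (or ANOVA estimators);
  effect sizes as partial ω² = σ²_effect / σ²_total; heritability as the
  strain intra-class correlation h² = σ²_strain / (σ²_strain + σ²_error)
  with a Searle-adjusted standard error for unbalanced designs; Storey
  q-values for FDR control; least-squares strain means and the
  pooled-vs-by-sex mapping policy.
* **Sub-population contrasts** — nested model with the alternate F ratio
  MS_subpop / MS_strain(subpop), because mice are replicates within strain.
* **QTL mapping** — Haley–Knott regression of strain means on expected
  D-allele dosage (LOD = (n/2)·log₁₀(RSS₀/RSS₁)) at markers and
  pseudomarkers (RI map expansion R = 4r/(1+6r)); genome-wide suggestive
  (P < 0.63) and significant (P < 0.05) thresholds from strain-label
  permutations; one-LOD support intervals and positional candidate genes.
* **Multi-trait factor analysis** — strain missingness filter (> 25%
  dropped), column-mean imputation, James–Stein/Schäfer–Strimmer shrinkage
  correlation (positive definite for n < p), parallel-analysis and
  optimal-coordinates factor counts, unrotated maximum-likelihood factor
  analysis by EM, Thomson factor scores F = Z·R⁻¹·Λ, and factor-score QTL
  mapping.
* **Extreme strains** — Mahalanobis D² with a χ² criterion over a
  correlated trait set.
* **Integration** — bipartite gene–phenotype graph over candidate and
  expression-correlate lists, connectivity ranking, and hypergeometric
  gene-set over-representation of the top 5%/10% slices.
* **Synthetic panels** — a generator producing genotypes (Markov-chain RI
  chromosomes), individual phenotypes with configured variance fractions,
  cis-driven expression, gene annotations and gene sets, so every stage is
  testable without external data.

## Worked example

```python
import riphenome as rp

cfg = rp.SimulationConfig(
    n_strains_per_subpop=(32, 37),          # older + recent lines
    traits=rp.default_trait_specs(40),
    qtl_spec=(rp.QTLEffect("m05_025", "trait010", a=0.6),),
    seed=1)
geno = rp.simulate_genotypes(cfg)
pheno = rp.simulate_phenotypes(geno, cfg)

table = rp.effects_table(pheno)
row = table.loc["trait010"]
print(f"p_strain={row.p_strain:.2e}  omega2={row.omega2_strain:.2f} "
      f"({row.effect_class})  h2_pooled={row.h2_pooled:.2f}")

means = rp.strain_means(pheno, "trait010")
sug, sig = rp.permutation_thresholds(means, geno, n_perm=1000, seed=1)
scan = rp.hk_scan(means, geno, step_cM=1.0)
for pk in rp.find_peaks(scan, sug, sig):
    print(f"chr{pk.chrom} @ {pk.pos_cM:.1f} cM  LOD={pk.lod:.2f} "
          f"({pk.classification})  1-LOD CI {pk.support_Mb[0]:.1f}-"
          f"{pk.support_Mb[1]:.1f} Mb")
```

prints

```
p_strain=2.98e-102  omega2=0.47 (large)  h2_pooled=0.48
chr5 @ 49.0 cM  LOD=13.06 (significant)  1-LOD CI 48.4-49.4 Mb
```

The trait was simulated with a polygenic strain variance fraction of 0.20
plus an additive QTL (a = 0.6) at marker `m05_025` (chromosome 5, 49.0
cM/Mb); the planted locus is recovered as a significant peak whose one-LOD
interval covers the true position, and the QTL pushes the realized strain
effect size (ω² = 0.47, h² ≈ 0.48) well above the configured polygenic
fraction, exactly as an additive major locus should.

The same analyses are available from the shell
(`riphenome simulate|effects|subpop|qtl|correlate|factors|outliers|integrate|run`),
and `riphenome run --out DIR --seed S` executes the whole graph on a
synthetic panel, writing TSV/JSON outputs plus a manifest of seeds and
thresholds.

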