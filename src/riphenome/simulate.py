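"""Synthetic RI panel generator.

Generates genotypes, individual phenotypes, expression matrices, gene
annotations and gene sets with the statistical structure the downstream
analyses assume, so that the whole pipeline is testable without external
data.

RI transmission is simulated as a marker-to-marker Markov chain along each
chromosome rather than by forward-in-time breeding: adjacent-marker
recombination uses the Haldane map function and the sib-mating RI expansion
``R = 4r / (1 + 6r)`` (Haldane & Waddington), which reproduces the expected
two-locus statistics of an inbred RI panel at a fraction of the cost.
Strains are fully inbred by default (no ``H`` calls emitted; ``H``/``U`` are
supported by the readers).

Phenotypes follow a strain/sex random-effects model per trait::

    y = mu + sum_m a_m * g_m + u_strain + s_sex + (us)_strain.sex + e

with ``g`` coded -1/+1 for B/D at planted QTL markers and random components
drawn to hit configured variance fractions (total non-QTL variance 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GenotypeMatrix, validate_phenotypes


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane recombination fraction for a map distance in centiMorgans."""
    return 0.5 * (1.0 - np.exp(-0.02 * np.asarray(d_cM, dtype=float)))


def ri_expansion(r: float | np.ndarray) -> float | np.ndarray:
    """Sib-mating RI map expansion: R = 4r / (1 + 6r)."""
    r = np.asarray(r, dtype=float)
    return 4.0 * r / (1.0 + 6.0 * r)


@dataclass(frozen=True)
class QTLEffect:
    """A planted additive QTL: adds ``a * g`` to one trait (g = -1/+1)."""

    marker: str
    trait: str
    a: float
    sex_specific: bool = False   # if True the effect acts in females only


@dataclass(frozen=True)
class TraitSpec:
    """Variance fractions for one trait; fractions must sum to 1."""

    v_strain: float
    v_sex: float
    v_interaction: float
    v_error: float
    battery: str = "battery1"

    def __post_init__(self) -> None:
        fr = (self.v_strain, self.v_sex, self.v_interaction, self.v_error)
        if any(v < 0 for v in fr):
            raise ValueError("variance fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-8:
            raise ValueError(f"variance fractions must sum to 1, got {sum(fr)}")


#: battery names mirroring a multi-site behavioral phenome survey
DEFAULT_BATTERIES = (
    "cocaine", "morphine", "ethanol1", "ethanol2", "general_behavior",
    "pain", "mdma", "vocalization", "neurogenesis", "adrenals",
)


def default_trait_specs(n_traits: int = 250,
                        batteries: Sequence[str] = DEFAULT_BATTERIES,
                        ) -> dict[str, TraitSpec]:
    """Deterministic trait panel: strain variance fractions span 0.05-0.7.

    Sex and strain-by-sex fractions cycle over {0, 0.02, 0.05, 0.10} so that
    a realistic minority of traits carry sex structure; the remainder is
    residual error. Traits are assigned to batteries in contiguous blocks.
    """
    v_strain = np.linspace(0.05, 0.70, n_traits)
    sex_cycle = (0.0, 0.02, 0.0, 0.05, 0.0, 0.10)
    int_cycle = (0.0, 0.0, 0.05, 0.0, 0.10, 0.02)
    per_battery = -(-n_traits // len(batteries))
    specs: dict[str, TraitSpec] = {}
    for i in range(n_traits):
        vs = float(v_strain[i])
        vx = sex_cycle[i % len(sex_cycle)]
        vi = int_cycle[i % len(int_cycle)]
        specs[f"trait{i + 1:03d}"] = TraitSpec(
            v_strain=vs, v_sex=vx, v_interaction=vi,
            v_error=1.0 - vs - vx - vi,
            battery=batteries[min(i // per_battery, len(batteries) - 1)],
        )
    return specs


@dataclass
class SimulationConfig:
    """Study design for the synthetic panel.

    Defaults emulate the expanded BXD survey conditions: two sub-populations
    (32 older + 37 recent lines), 3-11 mice per sex per strain, a 20 x 50
    marker grid over 100 cM chromosomes, ~250 traits with strain variance
    fractions spanning 0.05-0.7, and a handful of sub-population-private
    loci fixed in the older lines.
    """

    n_strains_per_subpop: tuple[int, ...] = (32, 37)
    subpop_names: tuple[str, ...] = ("TaylorI", "Recent")
    n_mice_per_sex_per_strain: tuple[int, int] = (3, 11)
    n_chromosomes: int = 20
    markers_per_chromosome: int = 50
    chrom_length_cM: float = 100.0
    mb_per_cM: float = 1.0
    traits: Mapping[str, TraitSpec] = field(default_factory=default_trait_specs)
    qtl_spec: tuple[QTLEffect, ...] = ()
    missing_rate: float = 0.0
    private_locus_count: int = 5
    n_probes: int = 500
    n_cis_probes: int = 25
    cis_gamma: float = 1.0
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if min(self.n_strains_per_subpop) < 1:
            raise ValueError("need at least one strain per sub-population")
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one marker")
        lo, hi = self.n_mice_per_sex_per_strain
        if lo < 1 or hi < lo:
            raise ValueError("invalid mice-per-sex-per-strain range")


def _marker_map(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        cm = np.linspace(0.0, config.chrom_length_cM,
                         config.markers_per_chromosome)
        for j, pos in enumerate(cm):
            rows.append((f"m{c:02d}_{j + 1:03d}", str(c), float(pos),
                         float(pos * config.mb_per_cM)))
    return pd.DataFrame(rows, columns=["marker", "chrom", "cM", "Mb"])


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       ) -> GenotypeMatrix:
    """Simulate fully inbred RI genotypes as a Markov chain per chromosome.

    The first marker of each chromosome is B or D with probability 0.5; each
    subsequent marker flips with the expanded recombination fraction
    ``R = 4r/(1+6r)`` derived from the Haldane ``r`` for the map step.
    ``private_locus_count`` markers are afterwards fixed for B in the first
    (older) sub-population while left segregating in the others.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mmap = _marker_map(config)
    strains, subpop = [], []
    i = 0
    for name, n in zip(config.subpop_names, config.n_strains_per_subpop):
        for _ in range(n):
            i += 1
            strains.append(f"RI{i:03d}")
            subpop.append(name)
    n_strains = len(strains)

    blocks = []
    for _, grp in mmap.groupby("chrom", sort=False):
        m = len(grp)
        R = ri_expansion(haldane_r(np.diff(grp["cM"].to_numpy())))
        g = np.empty((n_strains, m), dtype=np.int8)
        g[:, 0] = rng.random(n_strains) < 0.5
        flips = rng.random((n_strains, m - 1)) < R[None, :]
        for j in range(1, m):
            g[:, j] = g[:, j - 1] ^ flips[:, j - 1]
        blocks.append(g)
    geno = np.concatenate(blocks, axis=1)

    if config.private_locus_count > 0:
        private = rng.choice(geno.shape[1], size=config.private_locus_count,
                             replace=False)
        old = [k for k, sp in enumerate(subpop)
               if sp == config.subpop_names[0]]
        geno[np.ix_(old, private)] = 0      # fixed for B in the older set

    calls = pd.DataFrame(np.where(geno == 1, "D", "B"), index=strains,
                         columns=mmap["marker"])
    return GenotypeMatrix(calls=calls, marker_map=mmap,
                          subpopulation=pd.Series(subpop, index=strains,
                                                  name="subpopulation"))


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """Simulate individual animal records under the strain/sex model.

    Returns a long-format phenotype table (``animal, strain, sex, battery,
    trait, value``). Each strain is assigned one per-sex sample size drawn
    uniformly from the configured range (both sexes in equal numbers); random
    strain, sex, interaction and error components are drawn independently per
    trait with the configured variance fractions; planted QTL add ``a * g``
    on top (in females only when ``sex_specific``).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    strains = genotypes.strains
    known = set(genotypes.calls.columns)
    for q in config.qtl_spec:
        if q.marker not in known:
            raise ValueError(f"QTL marker {q.marker!r} not in genotype map")
        if q.trait not in config.traits:
            raise ValueError(f"QTL trait {q.trait!r} not in trait specs")

    lo, hi = config.n_mice_per_sex_per_strain
    n_per = rng.integers(lo, hi + 1, size=len(strains))
    frame_rows = []
    a_id = 0
    for s, n in zip(strains, n_per):
        for sex in ("F", "M"):
            for _ in range(int(n)):
                a_id += 1
                frame_rows.append((f"A{a_id:05d}", s, sex))
    animals = pd.DataFrame(frame_rows, columns=["animal", "strain", "sex"])
    strain_idx = animals["strain"].map(
        {s: k for k, s in enumerate(strains)}).to_numpy()
    is_f = (animals["sex"] == "F").to_numpy()
    n_animals = len(animals)

    dosage = genotypes.dosage()
    qtl_by_trait: dict[str, list[QTLEffect]] = {}
    for q in config.qtl_spec:
        qtl_by_trait.setdefault(q.trait, []).append(q)

    pieces = []
    for trait, spec in config.traits.items():
        u = rng.normal(0.0, np.sqrt(spec.v_strain), size=len(strains))
        inter = rng.normal(0.0, np.sqrt(spec.v_interaction),
                           size=(len(strains), 2))
        # a two-level +-delta contrast has variance component
        # sum(effect - mean)^2 / (levels - 1) = 2 delta^2, so delta is
        # sqrt(v/2) for the component to equal the configured fraction
        sex_eff = np.sqrt(spec.v_sex / 2.0)
        e = rng.normal(0.0, np.sqrt(spec.v_error), size=n_animals)
        y = (u[strain_idx]
             + np.where(is_f, sex_eff, -sex_eff)
             + inter[strain_idx, np.where(is_f, 0, 1)]
             + e)
        for q in qtl_by_trait.get(trait, ()):
            g = (2.0 * dosage[q.marker].to_numpy() - 1.0)[strain_idx]
            g = np.nan_to_num(g)
            y = y + q.a * g * (is_f if q.sex_specific else 1.0)
        piece = animals.copy()
        piece["battery"] = spec.battery
        piece["trait"] = trait
        piece["value"] = y
        pieces.append(piece)
    data = pd.concat(pieces, ignore_index=True)[
        ["animal", "strain", "sex", "battery", "trait", "value"]]
    if config.missing_rate > 0:
        data = inject_missing(data, config.missing_rate, rng=rng)
    return validate_phenotypes(data)


def inject_missing(values: pd.DataFrame, rate: float,
                   strain_dropout: Iterable[str] | None = None,
                   rng: np.random.Generator | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Set entries missing-at-random with probability ``rate``.

    Accepts either a wide strain-by-trait matrix or a long phenotype table
    (detected by the presence of a ``value`` column). Strains listed in
    ``strain_dropout`` additionally get strictly more than 25% of their
    traits blanked, to exercise the downstream missingness filter.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    out = values.copy()
    long_format = "value" in out.columns and "trait" in out.columns

    if long_format:
        if rate > 0:
            mask = rng.random(len(out)) < rate
            out.loc[mask, "value"] = np.nan
        if strain_dropout:
            traits = out["trait"].unique()
            k = int(np.floor(0.25 * len(traits))) + 1
            for s in strain_dropout:
                drop = rng.choice(traits, size=min(k, len(traits)),
                                  replace=False)
                out.loc[out["strain"].eq(s) & out["trait"].isin(drop),
                        "value"] = np.nan
        return out

    if rate > 0:
        mask = rng.random(out.shape) < rate
        out = out.mask(mask)
    if strain_dropout:
        k = int(np.floor(0.25 * out.shape[1])) + 1
        for s in strain_dropout:
            cols = rng.choice(out.columns, size=min(k, out.shape[1]),
                              replace=False)
            out.loc[s, cols] = np.nan
    return out


def make_gene_annotation(marker_map: pd.DataFrame,
                         gene_size_Mb: float = 1.0) -> pd.DataFrame:
    """Tile the simulated genome with non-overlapping half-open Mb genes."""
    if len(marker_map) == 0:
        raise ValueError("empty marker map")
    rows = []
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        end = float(np.ceil(grp["Mb"].max())) or gene_size_Mb
        starts = np.arange(0.0, end, gene_size_Mb)
        for i, st in enumerate(starts):
            rows.append((f"g{chrom}_{i + 1:04d}", chrom, float(st),
                         float(min(st + gene_size_Mb, end))))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start_Mb", "end_Mb"])


def make_genesets(annotation: pd.DataFrame, n_sets: int = 20,
                  sizes: tuple[int, int] = (10, 50),
                  seed: int = 0) -> dict[str, list[str]]:
    """Sample reproducible gene sets (GMT semantics) from the annotation."""
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    rng = np.random.default_rng(seed)
    genes = annotation["gene"].to_numpy()
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(sizes[0], min(sizes[1], len(genes)) + 1))
        sets[f"SET{i + 1:03d}"] = sorted(
            rng.choice(genes, size=size, replace=False).tolist())
    return sets


def simulate_expression(genotypes: GenotypeMatrix,
                        config: SimulationConfig | None = None,
                        annotation: pd.DataFrame | None = None,
                        cis: Sequence[tuple[str, str, float]] = (),
                        n_probes: int | None = None,
                        noise_sd: float | None = None,
                        tissue: str = "synthetic",
                        seed: int | None = None) -> ExpressionMatrix:
    """Simulate a probes-by-strains expression matrix.

    A configured subset of probes are *cis-driven*: their expression is
    ``gamma * g`` at a marker plus Gaussian noise, so expression-trait genetic
    correlation can be planted. ``cis`` entries are ``(probe_id, marker,
    gamma)`` and override the config's randomly chosen cis probes. Probes are
    assigned genes from ``annotation`` (the gene nearest the probe's cis
    marker; non-cis probes get genes round-robin); without an annotation the
    probe id doubles as the gene id.
    """
    config = config if config is not None else SimulationConfig()
    n_probes = config.n_probes if n_probes is None else n_probes
    noise_sd = config.expression_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(
        (config.seed + 2) if seed is None else seed)
    if annotation is not None and len(annotation) == 0:
        raise ValueError("empty annotation")

    probes = [f"probe{i + 1:05d}" for i in range(n_probes)]
    strains = genotypes.strains
    vals = rng.normal(0.0, noise_sd, size=(n_probes, len(strains)))

    if not cis and config.n_cis_probes > 0:
        idx = rng.choice(n_probes, size=min(config.n_cis_probes, n_probes),
                         replace=False)
        markers = rng.choice(genotypes.marker_map["marker"].to_numpy(),
                             size=len(idx), replace=False)
        cis = [(probes[i], m, config.cis_gamma)
               for i, m in zip(idx, markers)]

    dosage = genotypes.dosage()
    cis_marker: dict[str, str] = {}
    pi = {p: i for i, p in enumerate(probes)}
    for probe, marker, gamma in cis:
        if probe not in pi:
            raise ValueError(f"unknown probe {probe!r}")
        g = 2.0 * dosage[marker].to_numpy() - 1.0
        vals[pi[probe]] += gamma * np.nan_to_num(g)
        cis_marker[probe] = marker

    if annotation is None:
        gene_of = {p: p for p in probes}
    else:
        gene_of = {}
        ann = annotation.reset_index(drop=True)
        mm = genotypes.marker_map.set_index("marker")
        for j, p in enumerate(probes):
            if p in cis_marker:
                m = mm.loc[cis_marker[p]]
                on_chr = ann[ann["chrom"] == m["chrom"]]
                mid = (on_chr["start_Mb"] + on_chr["end_Mb"]) / 2.0
                gene_of[p] = on_chr["gene"].iloc[
                    int(np.argmin(np.abs(mid.to_numpy() - m["Mb"])))]
            else:
                gene_of[p] = ann["gene"].iloc[j % len(ann)]

    values = pd.DataFrame(vals, index=probes, columns=strains)
    return ExpressionMatrix(values=values,
                            probe_gene=pd.Series(gene_of, name="gene"),
                            tissue=tissue)
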