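import numpy as np
import pandas as pd
import pytest

import riphenome as rp


@pytest.fixture(scope="session")
def small_config() -> rp.SimulationConfig:
    """Compact panel: 24 strains, 3 chromosomes, 6 traits, one planted QTL."""
    traits = {
        "null_trait": rp.TraitSpec(0.0, 0.0, 0.0, 1.0, battery="b1"),
        "heritable": rp.TraitSpec(0.5, 0.0, 0.0, 0.5, battery="b1"),
        "sexed": rp.TraitSpec(0.3, 0.2, 0.0, 0.5, battery="b2"),
        "interacting": rp.TraitSpec(0.3, 0.0, 0.2, 0.5, battery="b2"),
        "qtl_trait": rp.TraitSpec(0.2, 0.0, 0.0, 0.8, battery="b3"),
        "weak": rp.TraitSpec(0.08, 0.0, 0.0, 0.92, battery="b3"),
    }
    return rp.SimulationConfig(
        n_strains_per_subpop=(12, 12), n_mice_per_sex_per_strain=(4, 4),
        n_chromosomes=3, markers_per_chromosome=30, chrom_length_cM=90.0,
        traits=traits,
        qtl_spec=(rp.QTLEffect("m02_015", "qtl_trait", a=0.8),),
        private_locus_count=2, seed=42)


@pytest.fixture(scope="session")
def small_panel(small_config):
    genotypes = rp.simulate_genotypes(small_config)
    phenotypes = rp.simulate_phenotypes(genotypes, small_config)
    return genotypes, phenotypes


@pytest.fixture(scope="session")
def tiled_annotation() -> pd.DataFrame:
    """100 contiguous 1-Mb genes on one chromosome."""
    return pd.DataFrame({
        "gene": [f"g{i:03d}" for i in range(100)],
        "chrom": "1",
        "start_Mb": np.arange(100, dtype=float),
        "end_Mb": np.arange(1, 101, dtype=float),
    })


def toy_phenotypes(cell_values: dict, n_per_cell: int = 1,
                   trait: str = "t") -> pd.DataFrame:
    """Build a long-format table from {(strain, sex): [values...]}."""
    rows = []
    for (strain, sex), values in cell_values.items():
        vals = values if hasattr(values, "__len__") else [values] * n_per_cell
        for v in vals:
            rows.append((f"a{len(rows)}", strain, sex, "b", trait, v))
    return pd.DataFrame(rows, columns=["animal", "strain", "sex",
                                       "battery", "trait", "value"])
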