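import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from polygs import (
    SimulationConfig,
    drop_genes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_reads,
)
from polygs.pedigree import Pedigree


@pytest.fixture
def toy_pedigree() -> Pedigree:
    """Founders a, b; full sibs c, d; e = a selfed."""
    return Pedigree(
        ids=["a", "b", "c", "d", "e"],
        sire=np.array([-1, -1, 0, 0, 0]),
        dam=np.array([-1, -1, 1, 1, 0]),
        ploidy=4,
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_founders=20,
        n_crosses=12,
        progeny_per_cross=6,
        n_markers=300,
        n_years=2,
        field_dims=(12, 10),
        seed=421,
    )


@pytest.fixture(scope="session")
def small_population(small_config):
    """20 founders + 72 progeny, 300 markers, reads at 73x, 2-year phenotypes."""
    ped = simulate_pedigree(small_config)
    rng = np.random.default_rng(small_config.seed + 1)
    freqs = rng.uniform(0.1, 0.9, small_config.n_markers)
    pop = drop_genes(ped, freqs, track_ibd=True, seed=small_config.seed + 2)
    reads = simulate_reads(pop.true_dosage, seed=small_config.seed + 3)
    phenotypes = simulate_phenotypes(pop, small_config, seed=small_config.seed + 4)
    return pop, reads, phenotypes


@pytest.fixture
def tidy_phenotypes() -> pd.DataFrame:
    """Tiny deterministic two-year phenotype table: y = year + genotype."""
    rows = []
    effects = {"g1": 0.0, "g2": 1.0, "g3": 2.0}
    for year, year_eff in ((1, 0.0), (2, 1.0)):
        for i, (g, eff) in enumerate(effects.items()):
            rows.append(
                {
                    "genotype": g,
                    "year": year,
                    "row": i + 1,
                    "column": 1,
                    "trait": "t",
                    "value": 10.0 + year_eff + eff,
                }
            )
    return pd.DataFrame(rows)
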