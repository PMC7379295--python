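import numpy as np
import pandas as pd
import pytest

from bilmap.io import ChromosomeTable, MarkerMap
from bilmap.sim import SimulationConfig, simulate_population


@pytest.fixture
def toy_map() -> MarkerMap:
    """Two chromosomes, markers every 2 Mbp starting at 2 Mbp."""
    rows = []
    for chrom in ("chr01", "chr02"):
        for i in range(5):
            rows.append((f"{chrom}_m{i + 1}", chrom, 2_000_000 * (i + 1)))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]))


@pytest.fixture
def toy_chrom_table() -> ChromosomeTable:
    return ChromosomeTable({"chr01": 12_000_000, "chr02": 12_000_000})


@pytest.fixture
def toy_genotypes(toy_map) -> pd.DataFrame:
    calls = [
        list("ABBAA") + list("AAAAA"),
        list("AAAHH") + list("AABBA"),
        list("AAAAA") + list("AAAAA"),
    ]
    return pd.DataFrame(calls, index=["L1", "L2", "L3"], columns=toy_map.marker_ids)


@pytest.fixture(scope="session")
def sim_small():
    """A small but realistic simulated BIL population (shared across tests)."""
    cfg = SimulationConfig(
        seed=11, n_lines=60, n_chromosomes=6, markers_per_chromosome=80
    )
    return simulate_population(cfg)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
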