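"""Shared fixtures: small synthetic systems built at test time."""

import numpy as np
import pandas as pd
import pytest

from sexscan import simdata
from sexscan.formats import SampleTable


@pytest.fixture(scope="session")
def tiny_config() -> simdata.SimConfig:
    """Two populations, short genome, one region of each deletion-free kind."""
    return simdata.SimConfig(
        seed=11,
        n_populations=2,
        males_per_pop=10,
        females_per_pop=10,
        chrom_lengths=[("chr1", 120_000), ("chrXY", 200_000)],
        region_specs=[
            simdata.RegionSpec(40_000, 50_000, "Y_SPECIFIC"),
            simdata.RegionSpec(90_000, 110_000, "Y_DIVERGED_MULTIHAP",
                               n_y_haplotypes=5, divergence=0.02),
            simdata.RegionSpec(140_000, 160_000, "Y_SWEPT", divergence=0.1),
        ],
        snp_density=0.005,
        depth=10.0,
        base_error_rate=0.0,
        coverage_bin=1000,
        coverage_overdispersion=0.05,
    )


@pytest.fixture(scope="session")
def tiny_system(tiny_config) -> simdata.SimSystem:
    return simdata.simulate_system(tiny_config)


@pytest.fixture()
def one_pop_table() -> SampleTable:
    return SampleTable(pd.DataFrame({
        "id": [f"M{i}" for i in range(10)] + [f"F{i}" for i in range(10)],
        "sex": ["M"] * 10 + ["F"] * 10,
        "population": "pop1",
    }))


def make_gt(rows: list[list[int]]) -> np.ndarray:
    """Genotype matrix literal (sites x individuals)."""
    return np.array(rows, dtype=np.int8)
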