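import numpy as np
import pandas as pd
import pytest

from hybridqtl import (
    FounderDivergence,
    MapSpec,
    QTLSpec,
    SimConfig,
    VarianceSpec,
    simulate_design,
)
from hybridqtl.datatypes import GeneticMap


@pytest.fixture(scope="session")
def small_design():
    """A modest factorial with one strong Dent-GCA QTL and parental reuse."""
    cfg = SimConfig(
        n_lines_per_population=40,
        map_spec=MapSpec(n_chromosomes=2, chrom_length_cM=100.0, n_markers_per_chrom=25),
        founder_divergence=FounderDivergence(p_polymorphic=0.7, p_shared_minor=0.5),
        qtl_spec=[QTLSpec(1, 50.0, [2.5, 0, 0, 0], [0, 0, 0, 0], np.zeros((4, 4)))],
        variance=VarianceSpec(sigma2_D=0.3, sigma2_F=0.3, sigma2_e=1.0, sigma2_env_plot=0.5),
        n_environments=4,
        seed=11,
    )
    return simulate_design(cfg)


@pytest.fixture(scope="session")
def null_design():
    """No QTL, no population contrasts: a pure-noise trait."""
    cfg = SimConfig(
        n_lines_per_population=20,
        map_spec=MapSpec(n_chromosomes=2, chrom_length_cM=100.0, n_markers_per_chrom=20),
        variance=VarianceSpec(0.0, 0.0, 1.0, 0.0),
        n_environments=2,
        seed=23,
    )
    return simulate_design(cfg)


@pytest.fixture
def two_marker_map():
    def make(distance_cM: float) -> GeneticMap:
        return GeneticMap(
            pd.DataFrame(
                {"chrom": [1, 1], "marker": ["m1", "m2"], "pos_cM": [0.0, distance_cM]}
            )
        )

    return make
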