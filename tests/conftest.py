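import numpy as np
import pytest

from tfosmap.formats import read_chains
from tfosmap.reciprocal_map import build_bijective_map
from tfosmap.synthetic import (
    LinkPlan,
    PeakPlan,
    SimulationParams,
    TurnoverPlan,
    plant_links,
    plant_peaks,
    plant_turnover,
    simulate_genome_pair,
)

# The worked two-block chain: chrT [10,40) <-> chrQ [50,80) with gapless
# blocks [10,20)<->[50,60) and [25,40)<->[65,80).
TWO_BLOCK_CHAIN = "chain 1000 chrT 100 + 10 40 chrQ 100 + 50 80 1\n10 5 5\n15\n"


@pytest.fixture(scope="session")
def two_block_map():
    chains = read_chains(TWO_BLOCK_CHAIN)
    return build_bijective_map(chains, {"chrT": 100}, {"chrQ": 100})


@pytest.fixture(scope="session")
def planted():
    """A full planted dataset: genome pair, map, peaks, turnover, links."""
    params = SimulationParams(seed=11, n_decoy_chains=6,
                              inversion_rate=1e-4)
    chains, truth = simulate_genome_pair(params)
    one_map = build_bijective_map(chains, truth.sizes_a, truth.sizes_b)
    rng = np.random.default_rng(12)
    peaks = plant_peaks(truth, PeakPlan(n_decoy_off_dhs=12), rng)
    turnover = plant_turnover(truth, TurnoverPlan(), rng)
    links = plant_links(truth, peaks, LinkPlan(), rng)
    return {
        "chains": chains,
        "truth": truth,
        "map": one_map,
        "peaks": peaks,
        "turnover": turnover,
        "links": links,
    }
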