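import numpy as np
import pytest

from coalpoly.simulate import PolyploidEvent, SimulationConfig, simulate_history

# dated diploid trees used throughout; one coalescent unit = 2 * 5e4 * 3 / 1e6
# = 0.3 Ma under the default population size and generation time
FOUR_DIPLOID_NEWICK = "((D1:2.4,D2:2.4):1.99,(D3:3.0,D4:3.0):1.39):0.0;"
HEXA_PARENTS_NEWICK = "(((D1:1.8,D2:1.8):1.2,D3:3.0):1.0,D4:4.0):0.39;"
THREE_DIPLOID_NEWICK = "((D1:1.8,D2:1.8):1.2,D3:3.0):1.39;"


@pytest.fixture
def rng():
    return np.random.default_rng(20220617)


def make_history(kind: str, seed: int, **kwargs) -> tuple:
    """Planted histories used by several tests: returns (history, config)."""
    if kind == "allo4":
        events = [PolyploidEvent("allo", "T1", ("D1", "D2"), origin_ma=0.9)]
        newick = FOUR_DIPLOID_NEWICK
    elif kind == "allo6":
        events = [
            PolyploidEvent("allo", "H1", ("D1", "D2", "D3"), origin_ma=0.9, ploidy=6)
        ]
        newick = HEXA_PARENTS_NEWICK
    elif kind == "auto4":
        events = [PolyploidEvent("auto", "A1", ("D1",), origin_ma=1.2, ploidy=4)]
        newick = FOUR_DIPLOID_NEWICK
    elif kind == "two_origins":
        events = [
            PolyploidEvent("allo", "T1", ("D1", "D2"), origin_ma=0.9),
            PolyploidEvent("allo", "T2", ("D1", "D3"), origin_ma=0.9),
        ]
        newick = THREE_DIPLOID_NEWICK
    else:  # pragma: no cover
        raise ValueError(kind)
    cfg = SimulationConfig(
        species_tree_newick=newick,
        polyploid_events=events,
        rng_seed=seed,
        **kwargs,
    )
    return simulate_history(cfg), cfg


def split_maps(gene_tree_samples, polyploid_samples):
    """diploid allele->species and polyploid allele->sample maps."""
    diploid_map, poly_alleles = {}, {}
    for gts in gene_tree_samples:
        for allele in gts.alleles:
            owner = allele.split(".")[0]
            if owner in polyploid_samples:
                poly_alleles[allele] = owner
            else:
                diploid_map[allele] = owner
    return diploid_map, poly_alleles
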