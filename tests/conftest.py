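import numpy as np
import pandas as pd
import pytest

from namqg.simulate import (GeneticMap, TraitArchitecture, TraitSpec,
                            simulate_map, simulate_plots, simulate_rils)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    return simulate_map(5, 50, 120.0, 1.5e8, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_map):
    """6 families x 30 RILs on the small map."""
    return simulate_rils(small_map, 6, 30, seed=12)


@pytest.fixture(scope="session")
def snp_panel():
    """Panel with a dense projected-SNP set and founder haplotypes."""
    gmap = simulate_map(3, 24, 100.0, 1e8, seed=21)
    snp_map = simulate_map(3, 120, 100.0, 1e8, seed=22, prefix="s")
    return simulate_rils(gmap, 4, 40, seed=23, snp_map=snp_map)


@pytest.fixture(scope="session")
def nam_plots():
    """Moderate NAM-style trial: 8 fams x 40 RILs, 3 envs, known targets."""
    gmap = simulate_map(5, 40, 120.0, 1.5e8, seed=31)
    pop = simulate_rils(gmap, 8, 40, seed=32)
    spec = TraitSpec(family=0.4, ril=0.6, env=0.5, fam_env=0.6, ril_env=0.6,
                     plant=0.8, mean=5.0)
    arch = TraitArchitecture(traits={"RPR": spec})
    plots = simulate_plots(pop, arch, 3, (20, 16), 1, seed=33)
    return pop, plots, spec
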