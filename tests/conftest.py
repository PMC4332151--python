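import numpy as np
import pytest

import photoclock as pc


@pytest.fixture(scope="session")
def params() -> pc.ParameterSet:
    return pc.default_parameters()


class SimCache:
    """Lazily entrained simulations shared across the whole test session."""

    def __init__(self):
        self._cache = {}

    def run(self, genotype="WT", hours=16.0, temperature="reference_22C",
            days=1) -> pc.SimulationResult:
        key = (genotype, float(hours), temperature, days)
        if key not in self._cache:
            p = pc.apply_temperature(pc.default_parameters(),
                                     pc.SCENARIOS[temperature])
            env = pc.Environment.make(hours, temperature=temperature)
            self._cache[key] = pc.simulate(p, env, pc.genotype(genotype),
                                           days=days)
        return self._cache[key]

    def series(self, species, **kw) -> pc.Timeseries:
        return pc.from_simulation(self.run(**kw), species)


@pytest.fixture(scope="session")
def sims() -> SimCache:
    return SimCache()


@pytest.fixture(scope="session")
def planted_matrix():
    """Planted 3-cluster synthetic expression matrix at the standard design
    (200 genes, 6 conditions x 12 timepoints, noise sd 0.5, fixed seed)."""
    m, labels, truth = pc.gen_cluster_matrix(200, noise_sd=0.5, seed=11)
    return m, labels, truth
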