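import numpy as np
import pytest

from hybridgp.evaluation import ModelBundle
from hybridgp.metabolome_prep import average_replicates, normalize
from hybridgp.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic dataset with planted metabolite-mediated signal."""
    cfg = SimulationConfig(
        n_parents=60, g=200, m=80, n_hybrids=150, seed=3,
        metabolite_signal_fraction=0.4, trait_h2=0.7,
    )
    return cfg, simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    cfg, (G, Mx, crosses, yp, yh, truth) = small_sim
    Ml = normalize(average_replicates(Mx))
    bundle = ModelBundle(
        G=G, Mline=Ml, crosses=crosses, hybrid_phenotypes=yh, parent_phenotypes=yp
    )
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
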