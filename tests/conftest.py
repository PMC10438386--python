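import numpy as np
import pytest

from landgea import synthetic


@pytest.fixture(scope="session")
def landscape():
    """30x30 landscape with three uncorrelated standardized layers."""
    spec = synthetic.LandscapeSpec(grid_rows=30, grid_cols=30, n_env=3,
                                   autocorr_range=3.0, seed=11)
    current, futures = synthetic.simulate_landscape(
        spec, {"late": {"env1": 1.0}})
    return current, futures


@pytest.fixture(scope="session")
def samples(landscape):
    current, _ = landscape
    return synthetic.simulate_samples(10, 12, current, seed=12)


@pytest.fixture(scope="session")
def gm_truth(landscape, samples):
    """Genotypes with 5 planted clines on env1 and 10% missingness."""
    current, _ = landscape
    truth = synthetic.TruthTable.template(5, ["env1"], effect_size=2.0,
                                          ancestral_K=3, target_fst=0.15)
    return synthetic.simulate_genotypes(samples, current, n_neutral=200,
                                        n_adaptive=5, truth=truth,
                                        missing_rate=0.1, seed=13)


@pytest.fixture(scope="session")
def gm_complete(landscape, samples):
    """Genotypes without missing calls (ready for factor models)."""
    current, _ = landscape
    truth = synthetic.TruthTable.template(5, ["env1"], effect_size=2.0,
                                          ancestral_K=3, target_fst=0.15)
    gm, truth_out = synthetic.simulate_genotypes(
        samples, current, n_neutral=200, n_adaptive=5, truth=truth,
        missing_rate=0.0, seed=13)
    return gm, truth_out
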