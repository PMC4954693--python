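import numpy as np
import pytest

from hetmix.model import CHParams, Dataset, DetectionParams, GeneModel
from hetmix.simulate import simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def medium_model():
    """Medium-difficulty gene with a good assay."""
    ch = CHParams(0.5, 10.0, 1.0)
    return GeneModel(ch, DetectionParams(9.0, 0.25))


@pytest.fixture
def sckc_data(medium_model, rng):
    return simulate_dataset(medium_model, 100, 100, 10, rng)


def random_gene_model(rng) -> GeneModel:
    """A random valid model over the region the sampler explores."""
    ch = CHParams(
        float(rng.uniform(0.05, 0.95)),
        float(rng.uniform(6.0, 14.0)),
        float(rng.uniform(0.3, 2.5)),
    )
    det = DetectionParams(float(rng.uniform(5.0, 13.0)), float(rng.uniform(0.1, 1.5)))
    return GeneModel(ch, det)


def synthetic_chain(draws: np.ndarray, param_names, logposts=None):
    """Wrap raw draws in a Chain without running the sampler."""
    from hetmix.mcmc import Bounds, Chain

    draws = np.asarray(draws, dtype=float)
    d = draws.shape[1]
    bounds = Bounds.two_condition() if d == 8 else Bounds.single_condition()
    if logposts is None:
        logposts = np.zeros(len(draws))
    return Chain(
        draws=draws,
        logposts=np.asarray(logposts, dtype=float),
        acceptance_rate=0.5,
        tuned_scales=np.ones(d),
        bounds=bounds,
        param_names=tuple(param_names),
    )
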