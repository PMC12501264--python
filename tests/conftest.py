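import warnings

import numpy as np
import pytest
import scipy.sparse as sp

import lifcrit as lc


@pytest.fixture()
def methods_p() -> lc.ReservoirParams:
    """Reference configuration: N=1000, theta=5, tau_ref=1, tau=0.01,
    alpha=0.01, beta=0.1, RI=1, dt=0.1."""
    return lc.methods_params()


@pytest.fixture()
def small_p() -> lc.ReservoirParams:
    """Downscaled network for fast simulator tests."""
    return lc.methods_params(n_neurons=100)


@pytest.fixture()
def single_neuron_p() -> lc.ReservoirParams:
    """Hand-traceable one-neuron network: one 1 mV kick per 0.1 ms step,
    threshold 5 mV, no leak, 1 ms refractory period."""
    return lc.ReservoirParams(
        n_neurons=1, threshold=5.0, tau_ref=1.0, tau=0.1, alpha=0.0,
        beta=0.5, input_groups=((1, 1.0),), dt=0.1,
    )


def zero_weights(n: int) -> lc.WeightMatrix:
    return lc.WeightMatrix(
        weights=sp.csc_matrix((n, n)), topology_kind="uniform_random", seed=0
    )


@pytest.fixture(autouse=True)
def _silence_validity_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="mean-field validity conditions violated"
        )
        yield


@pytest.fixture()
def raster_factory():
    """Build a SpikeRaster from an explicit 0/1 matrix."""

    def make(spikes, dt=0.1):
        spikes = np.asarray(spikes, np.uint8)
        p = lc.methods_params(n_neurons=spikes.shape[0])
        return lc.SpikeRaster(spikes=spikes, dt=dt, params_snapshot=p)

    return make
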