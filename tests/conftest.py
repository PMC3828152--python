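import numpy as np
import pytest

from spikepc import (CostSpec, DecoderSpec, KernelEnsembleConfig,
                     LinearSystemSpec, build_connectivity, make_kernels)


@pytest.fixture
def small_homogeneous():
    """Tiny homogeneous perfect-integrator network (N=20, gamma=0.1)."""
    cfg = KernelEnsembleConfig("homogeneous-signed", N=20, J=1, norm=0.1)
    dec = DecoderSpec(make_kernels(cfg), lambda_d=10.0)
    system = LinearSystemSpec(A=np.zeros((1, 1)))
    net = build_connectivity(dec, system, CostSpec(nu=1e-5, mu=1e-6))
    return net, system, dec


@pytest.fixture
def random_decoder():
    rng = np.random.default_rng(7)
    G = rng.standard_normal((2, 12)) * 0.1
    return DecoderSpec(G, lambda_d=8.0)
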