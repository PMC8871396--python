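import numpy as np
import pytest

from cortexwm import (LocalCircuitParams, ConnectomeBundle,
                      compute_balance_constants, reference_connectome,
                      build_network)


@pytest.fixture(scope="session")
def params():
    return LocalCircuitParams()


@pytest.fixture(scope="session")
def constants(params):
    return compute_balance_constants(params)


@pytest.fixture(scope="session")
def reference_bundle():
    return reference_connectome()


@pytest.fixture(scope="session")
def distributed_net(reference_bundle):
    return build_network(reference_bundle, mode="distributed")


def make_toy_bundle(n=2, fln=0.1, sln=0.5, excitability=None):
    """Tiny all-to-all bundle for oracle comparisons."""
    areas = [f"A{i:02d}" for i in range(n)]
    F = np.full((n, n), fln, dtype=float)
    np.fill_diagonal(F, 0.0)
    S = np.full((n, n), sln, dtype=float)
    np.fill_diagonal(S, 0.0)
    if excitability is None:
        excitability = np.linspace(0, 1, n)
    return ConnectomeBundle(areas, F, S,
                            excitability=np.asarray(excitability, float),
                            meta={"synthetic": True}).validate()


@pytest.fixture(scope="session")
def toy2_net():
    # both areas intrinsically bistable: memory survives isolation
    b = make_toy_bundle(2, excitability=[0.9, 1.0])
    return build_network(b, mode="custom", G=0.1, J_max=0.50, J_min=0.47)


@pytest.fixture(scope="session")
def toy3_net():
    b = make_toy_bundle(3, excitability=[0.5, 0.8, 1.0])
    return build_network(b, mode="custom", G=0.15, J_max=0.50, J_min=0.30)
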