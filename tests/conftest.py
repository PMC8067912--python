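import numpy as np
import pytest

from mrscan import (
    FixtureSpec,
    build_contacts,
    build_hessian,
    covariance_from_hessian,
    generate_helix,
)

R0 = 12.5
K_SPRING = 1.0
SIGMA = 0.3


@pytest.fixture(scope="session")
def helix12():
    return generate_helix(FixtureSpec(n_sites=12))


@pytest.fixture(scope="session")
def topo12(helix12):
    return build_contacts(helix12, R0)


@pytest.fixture(scope="session")
def cov12(helix12, topo12):
    hessian = build_hessian(helix12, topo12, k=K_SPRING)
    return covariance_from_hessian(hessian, kBT=1.0)


@pytest.fixture(scope="session")
def helix20():
    # mild jitter breaks the perfect helical symmetry
    return generate_helix(FixtureSpec(n_sites=20, jitter=0.2, seed=11))


@pytest.fixture(scope="session")
def topo20(helix20):
    return build_contacts(helix20, R0)


@pytest.fixture(scope="session")
def cov20(helix20, topo20):
    hessian = build_hessian(helix20, topo20, k=K_SPRING)
    return covariance_from_hessian(hessian, kBT=1.0)


@pytest.fixture(scope="session")
def chain_structure():
    """Near-linear chain: consecutive contacts only at a short cutoff."""
    rng = np.random.default_rng(5)
    n = 8
    coords = np.column_stack(
        [np.arange(n) * 3.8, rng.normal(0, 0.4, n), rng.normal(0, 0.4, n)]
    )
    from mrscan import CAStructure

    return CAStructure(tuple(f"A:{i+1}" for i in range(n)), coords)
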