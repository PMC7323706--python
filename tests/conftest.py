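import numpy as np
import pytest

from dtishape import AcquisitionProtocol, GradientScheme, default_protocol


@pytest.fixture(scope="session")
def protocol() -> AcquisitionProtocol:
    """Default one-b0 + 20-direction b=1000 acquisition, S0=1000."""
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def scheme() -> GradientScheme:
    return default_protocol()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_spd_tensors(rng: np.random.Generator, n: int,
                       scale: float = 1e-3) -> np.ndarray:
    """Random positive-definite tensors with diffusivities ~ scale."""
    from scipy.stats import special_ortho_group

    lam = rng.uniform(0.05, 2.0, size=(n, 3)) * scale
    R = special_ortho_group.rvs(3, size=n, random_state=rng)
    if n == 1:
        R = R[None]
    return np.einsum("nij,nj,nkj->nik", R, lam, R)
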