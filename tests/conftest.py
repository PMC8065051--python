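import numpy as np
import pytest

from dktihist.dki import DiffusionTensor, KurtosisTensor, reference_scheme


@pytest.fixture(scope="session")
def scheme():
    """The emulated acquisition: b = 0 + 30 directions x {100, 1000, 2000}."""
    return reference_scheme()


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def random_tensor_pair(rng: np.random.Generator) -> tuple[DiffusionTensor, KurtosisTensor]:
    """A physically plausible random (D, W) pair: positive-definite D with
    brain-like eigenvalues, moderate random kurtosis tensor."""
    lam = rng.uniform(0.3e-3, 2.5e-3, 3)
    rot = random_rotation(rng)
    dt = DiffusionTensor(rot @ np.diag(lam) @ rot.T)
    kt = KurtosisTensor.from_unique(rng.uniform(-0.3, 1.5, 15))
    return dt, kt


def random_valid_tensor_pair(rng: np.random.Generator):
    """A physiologically valid pair: brain-range diffusivities and
    non-negative directional kurtosis of order 1, random symmetry axis."""
    from dktihist.synthetic import RegionSpec, build_tensors

    d_axial = rng.uniform(0.5e-3, 2.0e-3)
    spec = RegionSpec(
        "rand",
        "WM",
        d_axial=d_axial,
        d_radial=rng.uniform(0.3e-3, d_axial),
        k_axial=rng.uniform(0.4, 2.0),
        k_radial=rng.uniform(0.4, 2.0),
        axis=tuple(rng.normal(size=3)),
    )
    return build_tensors(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
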