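import numpy as np
import pytest

from mvseg.core import SequenceStack
from mvseg.nn import kernels
from mvseg.phantom import PhantomSpec, RdWedge, desk_spec, generate_phantom


@pytest.fixture(scope="session", autouse=True)
def _warm_numba_kernels():
    """Compile the branch kernels once for the whole session."""
    kernels.warmup()


@pytest.fixture(scope="session")
def desk_subject():
    """One desk-scale phantom with all six classes present."""
    return generate_phantom(desk_spec(seed=3))


@pytest.fixture(scope="session")
def noiseless_subject():
    import dataclasses

    return generate_phantom(dataclasses.replace(desk_spec(seed=3), noise_sd=0.0))


@pytest.fixture(scope="session")
def random_stack():
    """A small random multi-sequence stack on a deliberately non-cubic grid."""
    rng = np.random.default_rng(42)
    shape = (17, 19, 23)
    return SequenceStack(
        {name: rng.normal(size=shape).astype(np.float32) for name in ("fiesta", "t2", "t1c")},
        voxel_spacing=(1.0, 1.0, 1.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_spec(seed: int = 0) -> PhantomSpec:
    """A very small phantom for fast training-loop tests."""
    return PhantomSpec(
        grid_shape=(30, 30, 30),
        voxel_spacing=(1.3, 1.3, 1.3),
        globe_radius=7.0,
        sclera_thickness=1.4,
        lens_semi_axes=(2.4, 1.8, 2.4),
        tumor_blobs=(((0.5, -1.8, -0.8), 3.0),),
        rd_wedge=RdWedge(thickness_mm=2.0),
        noise_sd=0.08,
        seed=seed,
    )
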