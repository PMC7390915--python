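import numpy as np
import pytest

from slicechain.phantom import PhantomSpec, generate_phantom
from slicechain.volume_io import BinaryMask, Case, CTVolume


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic default-spec phantom shared across tests."""
    return generate_phantom(PhantomSpec(), seed=7)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(noise_sd=0.0), seed=7)


def disk_mask(n: int, center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def disk():
    return disk_mask


@pytest.fixture
def cylinder_case():
    """A 24-slice case whose truth is the same disk on slices 5..18."""
    n = 64
    d = disk_mask(n, (32, 32), 9)
    vox = np.zeros((24, n, n), dtype=np.float32)
    mask = np.zeros((24, n, n), dtype=bool)
    for s in range(5, 19):
        vox[s] = 0.5 + 0.05 * d
        mask[s] = d
    spacing = (2.5, 0.98, 0.98)
    return Case(
        volume=CTVolume(voxels=vox, spacing=spacing),
        mask=BinaryMask(voxels=mask, spacing=spacing),
        case_id="cylinder",
    )
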