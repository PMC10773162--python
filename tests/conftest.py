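import numpy as np
import pytest

from dissectflow.fields import VelocityField4D
from dissectflow.rheology import PowerLawParams
from dissectflow.synthetic import AcquisitionParams, PhantomSpec, \
    make_phantom_field


@pytest.fixture(scope="session")
def plparams():
    return PowerLawParams()


@pytest.fixture(scope="session")
def quiet_acq():
    """Noise-free acquisition at the default MRI-like settings."""
    return AcquisitionParams(noise_sd_fraction_of_venc=0.0)


@pytest.fixture(scope="session")
def tube_field(quiet_acq):
    """Noise-free straight-tube phantom (16 voxels across, 1.25 mm)."""
    spec = PhantomSpec(kind="straight_tube", radius_mm=10.0, rng_seed=0)
    acq = AcquisitionParams(voxel_size_mm=1.25,
                            noise_sd_fraction_of_venc=0.0)
    field, mask = make_phantom_field(spec, acq)
    return spec, acq, field


@pytest.fixture(scope="session")
def two_lumen_field(quiet_acq):
    """Noise-free two-lumen phantom with a 56/44 TL/FL flow split."""
    spec = PhantomSpec(kind="two_lumen_dissection", radius_mm=10.0,
                       tl_flow_fraction=0.56, rng_seed=0)
    field, mask = make_phantom_field(spec, quiet_acq)
    return spec, field


def uniform_axial_field(speed=0.5, radius_mm=10.0, voxel_mm=1.25,
                        nz=9) -> VelocityField4D:
    """Tube-masked field with a constant axial velocity (m/s)."""
    n = int(np.ceil((2 * radius_mm + 4 * voxel_mm) / voxel_mm))
    coords = (np.arange(n) - (n - 1) / 2) * voxel_mm
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    mask2d = (X**2 + Y**2 < radius_mm**2).astype(np.uint8)
    mask = np.repeat(mask2d[:, :, None], nz, axis=2)
    v = np.zeros((4, n, n, nz, 3))
    v[..., 2] = speed * mask[None, :, :, :]
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[0, 3] = coords[0]
    affine[1, 3] = coords[0]
    times = 0.2 * np.arange(4)
    return VelocityField4D(v, mask, affine, times, 0.8)
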