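import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iraequant import (
    ImageGrid,
    OrganMask,
    PhantomSpec,
    ScanMeta,
    SUVVolume,
    build_phantom,
    default_uptake_model,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: Coarse phantom (6 mm voxels, same world-mm anatomy) used by the
#: statistical simulation suites to keep them fast.
COARSE_PHANTOM = PhantomSpec(dims=(43, 43, 64), spacing=(6.0, 6.0, 6.0))


@pytest.fixture(scope="session")
def default_mask():
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_mask():
    return build_phantom(COARSE_PHANTOM)


@pytest.fixture(scope="session")
def uptake_model():
    return default_uptake_model()


@pytest.fixture
def unit_grid():
    return ImageGrid(dims=(4, 4, 4), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def uniform_suv(unit_grid):
    def make(value=2.0, patient="P", day=0):
        return SUVVolume(
            grid=unit_grid,
            voxels=np.full(unit_grid.dims, value, dtype=np.float32),
            meta=ScanMeta(patient_id=patient, scan_day=day, suv_precomputed=True),
        )

    return make


@pytest.fixture
def block_mask(unit_grid):
    """Mask with a 2x2x2 bowel block at the origin corner."""
    labels = np.zeros(unit_grid.dims, dtype=np.int16)
    labels[:2, :2, :2] = 1
    return OrganMask(grid=unit_grid, labels=labels)
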