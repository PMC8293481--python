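import numpy as np
import pytest

from mtlmorph import CohortSimSpec, simulate_cohort
from mtlmorph.stats import encode_covariates
from mtlmorph.thickness import BinaryMask, Landmark


def make_slab_mask(n_planes: int = 11, spacing: float = 0.2, lateral: int = 21) -> BinaryMask:
    """Axis-aligned slab of ``n_planes`` consecutive foreground z-planes
    centered in a background grid."""
    nz = n_planes + 10
    values = np.zeros((lateral, lateral, nz), dtype=bool)
    z0 = (nz - n_planes) // 2
    values[:, :, z0 : z0 + n_planes] = True
    return BinaryMask(values=values, spacing=(spacing, spacing, spacing))


def slab_center_dot(mask: BinaryMask) -> tuple[float, float, float]:
    idx = np.array(mask.shape) // 2
    return tuple(idx * np.array(mask.spacing))


@pytest.fixture
def slab_mask() -> BinaryMask:
    return make_slab_mask()


@pytest.fixture
def erc_dot(slab_mask) -> Landmark:
    return Landmark(subregion="ERC", location_index=1, position=slab_center_dot(slab_mask))


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort under the default study conditions (n = 58)."""
    table = simulate_cohort(CohortSimSpec(seed=20210721))
    return encode_covariates(table)
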