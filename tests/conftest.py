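"""Shared fixtures: small phantoms and fast run configurations.

Unit tests run on a reduced 48x48x32 phantom (same anisotropic spacing as
the default) so a full pipeline pass takes a few seconds; the acceptance
tests use the default full-size phantom.
"""

import numpy as np
import pytest

from cascade_wmh import PhantomSpec, RunConfig, generate_phantom


def small_spec(**overrides) -> PhantomSpec:
    base = dict(
        grid_shape=(48, 48, 32),
        spacing_mm=(1.0, 1.0, 2.0),
        brain_radii_mm=(21.0, 21.0, 28.0),
        ventricle_radii_mm=(4.0, 9.0, 5.0),
        ventricle_offset_mm=6.0,
        cortical_thickness_mm=3.0,
        lesion_count=4,
        lesion_radius_range_mm=(2.5, 5.0),
        seed=1,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def small_config(**overrides) -> RunConfig:
    base = dict(
        seed=1,
        null_sample_size=2000,
        svm_subsample=3000,
        min_normal_voxels=300,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def small_phantom():
    """(study, truth) for a small 4-lesion phantom, all four sequences."""
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_lesion_free():
    return generate_phantom(small_spec(lesion_count=0))


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
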