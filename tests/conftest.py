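import numpy as np
import pytest

from lawmap.geometry import PatchSpec
from lawmap.phantom import SubjectParams
from lawmap.volume import CHAMBER, WALL, GridSpec, LabeledVolume


def make_sphere_params(r=20.0, t=2.0, f=1.0, sigma=0.0, patches=()):
    """Concentric-sphere subject with analytic index values."""
    return SubjectParams(
        group="control",
        inner_radii_mm=(r, r, r),
        mean_thickness_mm=t,
        thickness_sd_mm=sigma,
        patch_spec=tuple(patches),
        mapped_fraction=f,
        bsa_m2=1.73,
        covariates={},
        target_indices={},
        seed=0,
    )


def make_slab_volume(k=4, h=0.5, n=32, z_split=10):
    """Flat slab: chamber below z_split, k wall layers above, background rest.

    The slab spans the full lateral extent, so every thickness sample is
    exactly k*h by the center-to-center decomposition.
    """
    lab = np.zeros((n, n, n), np.uint8)
    lab[:, :, :z_split] = CHAMBER
    lab[:, :, z_split : z_split + k] = WALL
    return LabeledVolume(labels=lab, grid=GridSpec.centered((n, n, n), h))


def make_small_ellipsoid_params(sigma=0.3):
    """Ellipsoid phantom small enough for a 32^3 lattice at 0.8 mm."""
    patches = (PatchSpec(center=(0.0, 0.0, 1.0), width_rad=0.6, amplitude=1.0),)
    return SubjectParams(
        group="control",
        inner_radii_mm=(7.5, 7.2, 6.8),
        mean_thickness_mm=1.6,
        thickness_sd_mm=sigma,
        patch_spec=patches if sigma > 0 else (),
        mapped_fraction=1.0,
        bsa_m2=1.73,
        covariates={},
        target_indices={},
        seed=0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
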