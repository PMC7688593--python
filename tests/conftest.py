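"""Shared fixtures: desk-scale phantoms reused across the suite.

The "small" phantom (64^3 at 1.5 mm labels, 32^3 at 3 mm PET) keeps unit
tests fast; the default-size phantom (96^3 at 1 mm) is reserved for the
acceptance checks.
"""

import warnings

import pytest

from petpor.phantom import PhantomSpec, default_pet_grid, simulate_pet_scan
from petpor.psf import PSFModel
from petpor.studies import standard_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        shape=(64, 64, 64), voxel_mm=1.5, pet_shape=(32, 32, 32), pet_voxel_mm=3.0
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(LabelMap incl. shell, truth activities, spec) on the fast grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return standard_phantom(small_spec)


@pytest.fixture(scope="session")
def small_pet_clean(small_phantom):
    """Noise-free, perfectly registered PET on the label grid."""
    labels, truth, spec = small_phantom
    return simulate_pet_scan(labels, truth, None, PSFModel(spec.psf_fwhm_mm), 0.0)


@pytest.fixture(scope="session")
def small_pet_native(small_phantom):
    """Noise-free, perfectly registered PET on the coarser native PET grid."""
    labels, truth, spec = small_phantom
    return simulate_pet_scan(
        labels, truth, None, PSFModel(spec.psf_fwhm_mm), 0.0,
        pet_grid=default_pet_grid(spec),
    )
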