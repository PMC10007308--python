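"""Shared fixtures: calibrated materials, small phantoms and configs."""

import numpy as np
import pytest

from thzleaf import (
    DebyeParams,
    DryingCurve,
    LeafPhantom,
    TDSConfig,
    calibrate_absorption,
    dry_matter_spectrum,
    generate_phantom,
    water_permittivity,
)

#: Published absorption anchor: liquid water at the QCL carrier frequency.
WATER_ANCHOR = (2.71, 500.0)


@pytest.fixture(scope="session")
def water_params():
    return calibrate_absorption(DebyeParams(), [WATER_ANCHOR])


@pytest.fixture(scope="session")
def materials(water_params):
    """(water, dry) spectra factory on an arbitrary THz grid."""
    def make(freq_grid):
        fg = np.atleast_1d(np.asarray(freq_grid, float))
        return water_permittivity(fg, water_params), dry_matter_spectrum(fg)
    return make


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom("parallel_venation", (40, 45), seed=2)


@pytest.fixture(scope="session")
def default_curve():
    return DryingCurve()


@pytest.fixture(scope="session")
def frozen_curve():
    """Effectively static leaf (rates ~ 0, ordering constraints respected)."""
    return DryingCurve(rate_fast=3e-9, rate_plateau=0.0, rate_slow=2e-9)


@pytest.fixture(scope="session")
def small_tds_config():
    return TDSConfig(grid=(40, 45), extent_mm=(8.0, 9.0), dynamic_range_db=None)


def uniform_phantom(shape=(8, 8), f_water=0.25, f_dry=0.15,
                    thickness_um=200.0) -> LeafPhantom:
    """Structureless all-leaf phantom for inverse-model tests."""
    ones = np.ones(shape)
    return LeafPhantom(
        pixel_pitch_um=200.0,
        water_fraction=f_water * ones,
        dry_fraction=f_dry * ones,
        thickness_um=thickness_um * ones,
        vein_mask=np.zeros(shape, bool),
        leaf_mask=np.ones(shape, bool),
        seed=0,
    )
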