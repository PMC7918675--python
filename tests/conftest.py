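import numpy as np
import pytest

from lipidmsot import (
    KineticParams,
    PhantomConfig,
    build_forearm_phantom,
    load_spectral_table,
    simulate_study,
)
from lipidmsot.simulate import AcquisitionSchedule

# Mean kinetics of the four-subject pilot cohort: fractional increase A and
# peak time tp per compartment (gamma-variate shape alpha = 3 throughout).
MEAN_KINETICS = {
    "vein": KineticParams(amplitude=0.839, peak_time=187.5),
    "artery": KineticParams(amplitude=0.634, peak_time=232.5),
    "muscle": KineticParams(amplitude=1.208, peak_time=180.0),
    "fat": KineticParams(amplitude=0.328, peak_time=217.5),
}


@pytest.fixture(scope="session")
def table():
    return load_spectral_table()


def small_phantom_config(**overrides):
    """A 160x160 phantom that keeps simulation-heavy tests fast."""
    kwargs = dict(
        height=160,
        width=160,
        pixel_pitch=0.1,
        skin_row=20,
        skin_thickness=1.0,
        fat_thickness_range=(3.0, 4.0),
        vein_radius_range=(0.7, 0.9),
        artery_radius_range=(0.7, 0.9),
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_geometry():
    return build_forearm_phantom(small_phantom_config(), seed=7)


@pytest.fixture(scope="session")
def small_study(small_geometry):
    """Seeded 13-point single-wavelength (930 nm) study on the small phantom."""
    schedule = AcquisitionSchedule(wavelengths=np.array([930.0]))
    return simulate_study(
        small_geometry, MEAN_KINETICS, schedule=schedule, noise_frac=0.02, seed=7
    )
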