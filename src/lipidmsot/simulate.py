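"""Forward simulation of multispectral optoacoustic studies.

Emits reconstructed-domain single-wavelength images directly (no acoustic
modeling): per-pixel signal is the compartment absorption coefficient at the
shot wavelength times a depth-dependent light fluence, smoothed by the
system point-spread function and corrupted by additive Gaussian noise. A
postprandial study is a stack of such frames over an acquisition schedule
(default 13 time points at 30-min intervals over 6 h, 28 wavelengths
700-970 nm), with ground-truth compartment masks and kinetic parameters
carried along so the analysis pipeline can be validated end to end.

The lipid kinetics multiplier scales the whole absorption of its
compartment, making the compartment-mean 930-nm signal exactly proportional
to the injected multiplier m(t); see docs/methods.md for why this
simplification is used instead of scaling the lipid concentration alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .kinetics import KineticParams, lipid_timecourse
from .phantom import Compartment, TissueGeometry
from .spectra import ChromophoreMixture, SpectralTable, mixture_mu_a

__all__ = [
    "AcquisitionSchedule",
    "MultispectralStudy",
    "DEFAULT_MIXTURES",
    "fluence",
    "default_mu_eff",
    "simulate_frame",
    "simulate_study",
    "average_frames",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# Compartment composition reflecting each tissue's optoacoustic appearance:
# vessels blood-dominated (artery oxygenated, vein mixed), muscle
# water/blood-rich with little lipid, subcutaneous fat lipid-dominated.
DEFAULT_MIXTURES: dict[str, ChromophoreMixture] = {
    "skin": ChromophoreMixture({"Hb": 0.06, "HbO2": 0.10, "lipid": 0.35, "water": 0.40}),
    "fat": ChromophoreMixture({"Hb": 0.02, "HbO2": 0.03, "lipid": 1.00, "water": 0.15}),
    "muscle": ChromophoreMixture({"Hb": 0.12, "HbO2": 0.18, "lipid": 0.12, "water": 0.70}),
    "artery": ChromophoreMixture({"Hb": 0.10, "HbO2": 0.90, "lipid": 0.05, "water": 0.80}),
    "vein": ChromophoreMixture({"Hb": 0.45, "HbO2": 0.45, "lipid": 0.05, "water": 0.80}),
}


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Measurement time points (minutes) and wavelength grid (nm).

    Default: fasting scan at t=0 then every 30 min for 6 h (13 points).
    Shortened or irregular schedules (e.g. a subject stopping early) are
    supported as long as times are unique, ascending and start at 0.
    """

    time_points: np.ndarray = field(
        default_factory=lambda: np.arange(0, 361, 30, dtype=float)
    )
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(700, 971, 10, dtype=float)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        if t.size == 0 or wl.size == 0:
            raise ValueError("schedule must have at least one time point and wavelength")
        if t[0] != 0:
            raise ValueError("first time point must be 0 (fasting baseline)")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be unique and ascending")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be unique and ascending")
        object.__setattr__(self, "time_points", t)
        object.__setattr__(self, "wavelengths", wl)


@dataclass
class MultispectralStudy:
    """A simulated postprandial acquisition with its ground truth.

    frames : (n_times, n_wavelengths, H, W) float32 signal images
    """

    frames: np.ndarray
    schedule: AcquisitionSchedule
    geometry: TissueGeometry
    kinetics: Mapping[str, KineticParams]
    mixtures: Mapping[str, ChromophoreMixture]
    seed: int

    @property
    def ground_truth_masks(self) -> dict[str, np.ndarray]:
        return {name: self.geometry.mask(name) for name in self.kinetics}

    def frame(self, time_index: int, wavelength: float) -> np.ndarray:
        wl_idx = _wavelength_index(self.schedule.wavelengths, wavelength)
        return self.frames[time_index, wl_idx]

    def kinetics_json(self) -> str:
        return json.dumps(
            {
                name: {
                    "baseline": k.baseline,
                    "amplitude": k.amplitude,
                    "peak_time": k.peak_time,
                    "shape": k.shape,
                }
                for name, k in self.kinetics.items()
            }
        )


def _wavelength_index(grid: np.ndarray, wavelength: float) -> int:
    hits = np.nonzero(np.isclose(grid, wavelength))[0]
    if hits.size == 0:
        from .spectra import GridError

        raise GridError(
            f"wavelength {wavelength} nm not in the study grid "
            f"({grid.min():.0f}-{grid.max():.0f} nm)"
        )
    return int(hits[0])


def fluence(wavelength: float, depth: float | np.ndarray, mu_eff: float) -> float | np.ndarray:
    """Relative light fluence exp(-mu_eff * depth) at depth (mm) below the skin.

    A single bulk effective attenuation per wavelength; no per-tissue
    heterogeneity and no fluence correction downstream, mirroring how the
    measured data are analysed (relative signals only).
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0 mm")
    out = np.exp(-mu_eff * d)
    return float(out) if np.isscalar(depth) else out


def default_mu_eff(wavelength: float | np.ndarray) -> float | np.ndarray:
    """Bulk effective attenuation (1/mm), decreasing mildly across the NIR.

    ~1.0 /cm at 700 nm to ~0.6 /cm at 970 nm — typical soft-tissue scale.
    """
    wl = np.asarray(wavelength, dtype=float)
    out = 0.10 - 1.5e-4 * (wl - 700.0)
    return float(out) if np.isscalar(wavelength) else out


def simulate_frame(
    geometry: TissueGeometry,
    mixtures: Mapping[str, ChromophoreMixture],
    wavelength: float,
    table: SpectralTable,
    psf_fwhm: float = 0.3,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    mu_eff: float | None = None,
) -> np.ndarray:
    """One single-wavelength signal image for given compartment mixtures.

    signal = mu_a(compartment, wavelength) * fluence(wavelength, depth),
    blurred with a Gaussian PSF of the given FWHM (mm), plus seeded additive
    Gaussian noise. Background (coupling medium) contributes no signal.
    """
    if psf_fwhm < 0:
        raise ValueError("psf_fwhm must be >= 0 mm")
    mu_by_label = np.zeros(max(Compartment.NAMES) + 1, dtype=float)
    for name, mix in mixtures.items():
        mu_by_label[Compartment.BY_NAME[name]] = mixture_mu_a(mix, table, wavelength)
    att = default_mu_eff(wavelength) if mu_eff is None else mu_eff
    img = mu_by_label[geometry.label_map] * fluence(wavelength, geometry.depth_mm(), att)
    if psf_fwhm > 0:
        img = gaussian_filter(img, sigma=psf_fwhm / FWHM_TO_SIGMA / geometry.pixel_pitch)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img.astype(np.float32)


def reference_skin_signal(
    geometry: TissueGeometry,
    mixtures: Mapping[str, ChromophoreMixture],
    table: SpectralTable,
    wavelength: float = 930.0,
    psf_fwhm: float = 0.3,
) -> float:
    """Mean noise-free signal over skin pixels; the unit for noise fractions."""
    frame = simulate_frame(geometry, mixtures, wavelength, table, psf_fwhm=psf_fwhm)
    return float(frame[geometry.mask("skin")].mean())


def simulate_study(
    geometry: TissueGeometry,
    kinetics: Mapping[str, KineticParams],
    schedule: AcquisitionSchedule | None = None,
    table: SpectralTable | None = None,
    mixtures: Mapping[str, ChromophoreMixture] | None = None,
    noise_frac: float = 0.02,
    psf_fwhm: float = 0.3,
    seed: int = 0,
    dtype: np.dtype | type = np.float32,
) -> MultispectralStudy:
    """Simulate a full postprandial study; bit-identical for a fixed seed.

    ``kinetics`` maps compartment names (vein, artery, muscle, fat) to their
    lipid kinetic parameters; compartments without an entry stay static.
    ``noise_frac`` is the additive noise sigma as a fraction of the mean
    skin-surface signal at 930 nm (or the first grid wavelength if 930 is
    not acquired); default 2%.
    """
    from .spectra import load_spectral_table

    schedule = schedule or AcquisitionSchedule()
    table = table if table is not None else load_spectral_table()
    mixtures = dict(mixtures or DEFAULT_MIXTURES)
    unknown = set(kinetics) - set(mixtures)
    if unknown:
        raise ValueError(f"kinetics given for compartments without mixtures: {unknown}")

    times = schedule.time_points
    wls = schedule.wavelengths
    h, w = geometry.shape
    labels = geometry.label_map
    depth = geometry.depth_mm()

    # per-label absorption at every wavelength, and per-label time multiplier
    n_labels = max(Compartment.NAMES) + 1
    base_mu = np.zeros((n_labels, wls.size))
    for name, mix in mixtures.items():
        lbl = Compartment.BY_NAME[name]
        base_mu[lbl] = [mixture_mu_a(mix, table, wl) for wl in wls]
    mult = np.ones((n_labels, times.size))
    for name, params in kinetics.items():
        mult[Compartment.BY_NAME[name]] = lipid_timecourse(params, times)

    fluence_maps = np.stack([fluence(wl, depth, default_mu_eff(wl)) for wl in wls])

    ref_wl = 930.0 if np.any(np.isclose(wls, 930.0)) else float(wls[0])
    noise_sigma = (
        noise_frac * reference_skin_signal(geometry, mixtures, table, ref_wl, psf_fwhm)
        if noise_frac > 0
        else 0.0
    )

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51]))
    sigma_px = psf_fwhm / FWHM_TO_SIGMA / geometry.pixel_pitch if psf_fwhm > 0 else 0.0
    frames = np.empty((times.size, wls.size, h, w), dtype=dtype)
    for ti in range(times.size):
        mu_t = base_mu * mult[:, ti : ti + 1]
        for wi in range(wls.size):
            img = mu_t[labels, wi] * fluence_maps[wi]
            if sigma_px > 0:
                img = gaussian_filter(img, sigma=sigma_px)
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, size=img.shape)
            frames[ti, wi] = img
    return MultispectralStudy(
        frames=frames,
        schedule=schedule,
        geometry=geometry,
        kinetics=dict(kinetics),
        mixtures=mixtures,
        seed=seed,
    )


def average_frames(stack: np.ndarray) -> np.ndarray:
    """Mean of k repeat frames (k, H, W) -> (H, W); optional pre-step before
    ROI analysis when a time point was recorded as a short burst."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("expected a (k, H, W) stack with k >= 1")
    return arr.mean(axis=0)
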