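"""Near-infrared chromophore absorption spectra and linear mixtures.

Optoacoustic contrast in the 700-970 nm window is dominated by four tissue
chromophores: deoxygenated hemoglobin (Hb), oxygenated hemoglobin (HbO2),
lipid, and water. Single-wavelength images read out their combined
absorption: 750 nm is Hb-weighted, 850 nm HbO2-weighted, and 930 nm sits on
the NIR lipid absorption peak, which is why lipid content is tracked there.

Absolute calibration is irrelevant for the relative-signal analyses built on
top of this module, so absorption values are stored in relative units on the
fixed 10-nm acquisition grid; no interpolation between grid points is
offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "SpectralTable",
    "ChromophoreMixture",
    "load_spectral_table",
    "absorption_at",
    "mixture_mu_a",
    "unmix_linear",
    "GridError",
    "ChromophoreError",
]

DEFAULT_WAVELENGTHS = np.arange(700, 971, 10)


class GridError(ValueError):
    """Requested wavelength is not on the acquisition grid."""


class ChromophoreError(KeyError):
    """Requested chromophore is not in the table."""


@dataclass(frozen=True)
class SpectralTable:
    """Per-chromophore absorption on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm (default 700..970 at 10 nm steps).
    absorption
        Mapping chromophore name -> array of positive absorption values,
        one per wavelength, in relative units.
    """

    wavelengths: np.ndarray
    absorption: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or len(wl) < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 entries")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing and unique")
        object.__setattr__(self, "wavelengths", wl)
        absn = {}
        for name, values in self.absorption.items():
            v = np.asarray(values, dtype=float)
            if v.shape != wl.shape:
                raise ValueError(
                    f"chromophore {name!r}: {v.size} values for {wl.size} wavelengths"
                )
            if not np.all(v > 0):
                raise ValueError(f"chromophore {name!r}: absorption values must be > 0")
            absn[name] = v
        object.__setattr__(self, "absorption", absn)

    @property
    def chromophores(self) -> tuple[str, ...]:
        return tuple(self.absorption)

    def index_of(self, wavelength: float) -> int:
        """Grid index of ``wavelength``; GridError names the nearest grid points."""
        wl = self.wavelengths
        hits = np.nonzero(np.isclose(wl, wavelength))[0]
        if hits.size == 0:
            below = wl[wl < wavelength]
            above = wl[wl > wavelength]
            nearest = sorted(
                x for x in (below[-1] if below.size else None,
                            above[0] if above.size else None)
                if x is not None
            )
            raise GridError(
                f"wavelength {wavelength} nm is off the acquisition grid; "
                f"nearest grid points: {[int(x) for x in nearest]}"
            )
        return int(hits[0])

    def spectrum(self, chromophore: str) -> np.ndarray:
        if chromophore not in self.absorption:
            raise ChromophoreError(
                f"unknown chromophore {chromophore!r}; available: {list(self.absorption)}"
            )
        return self.absorption[chromophore]


@dataclass(frozen=True)
class ChromophoreMixture:
    """Non-negative chromophore weights of one tissue compartment.

    Concentrations are on an arbitrary relative scale; only ratios matter
    for the contrast arguments downstream.
    """

    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        conc = {str(k): float(v) for k, v in self.concentrations.items()}
        for name, c in conc.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}: {c}")
        object.__setattr__(self, "concentrations", conc)

    def scaled(self, factor: float) -> "ChromophoreMixture":
        if factor < 0:
            raise ValueError(f"negative scale factor: {factor}")
        return ChromophoreMixture({k: v * factor for k, v in self.concentrations.items()})


def load_spectral_table(source: str | Path = "nir") -> SpectralTable:
    """Load a spectral table from the packaged data or a CSV path.

    The packaged table (``source="nir"``) compiles literature hemoglobin
    extinction and lipid/water absorption values resampled to the 28-point
    700-970 nm grid, rescaled to comparable relative units.
    CSV layout: header ``wavelength_nm,Hb,HbO2,lipid,water``.
    """
    if source == "nir":
        ref = resources.files("lipidmsot.data") / "nir_chromophore_spectra.csv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectral CSV must have a 'wavelength_nm' column")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    absorption = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "wavelength_nm"
    }
    return SpectralTable(wavelengths=wl, absorption=absorption)


def absorption_at(table: SpectralTable, chromophore: str, wavelength: float) -> float:
    """Stored absorption of ``chromophore`` at a grid ``wavelength`` (no interpolation)."""
    return float(table.spectrum(chromophore)[table.index_of(wavelength)])


def mixture_mu_a(
    mixture: ChromophoreMixture, table: SpectralTable, wavelength: float
) -> float:
    """Absorption coefficient of a mixture: sum_i c_i * eps_i(lambda), relative units."""
    idx = table.index_of(wavelength)
    return float(
        sum(c * table.spectrum(name)[idx] for name, c in mixture.concentrations.items())
    )


def mixture_spectrum(mixture: ChromophoreMixture, table: SpectralTable) -> np.ndarray:
    """Mixture absorption on the full grid (vectorised mixture_mu_a)."""
    out = np.zeros_like(table.wavelengths, dtype=float)
    for name, c in mixture.concentrations.items():
        out += c * table.spectrum(name)
    return out


def unmix_linear(
    pixel_spectrum: Sequence[float],
    table: SpectralTable,
    chromophores: Sequence[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Non-negative least-squares decomposition of a pixel spectrum.

    Solves ``min ||A w - s||`` subject to ``w >= 0`` where the columns of A
    are the requested chromophore spectra. Returns the weight per
    chromophore and the residual norm.
    """
    s = np.asarray(pixel_spectrum, dtype=float)
    if s.shape != table.wavelengths.shape:
        raise ValueError(
            f"pixel spectrum has {s.size} entries, grid has {table.wavelengths.size}"
        )
    names = list(chromophores) if chromophores is not None else list(table.chromophores)
    if not names:
        raise ValueError("at least one chromophore must be requested")
    basis = np.column_stack([table.spectrum(n) for n in names])
    weights, residual = nnls(basis, s)
    return dict(zip(names, map(float, weights))), float(residual)
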