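"""Wavelength grid, spectrum container and spectrum generators.

Every spectral quantity in the simulation — illumination power, sensor
sensitivity, stain optical density, sample transmittance, observer
colour-matching functions — lives on one shared, fixed wavelength grid.
The default grid covers the visible band from 405 nm to 700 nm in 5 nm
steps (60 sample points).  Mixing spectra from different grids is an error,
never a silent resampling.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import GridMismatchError, InvalidInputError

ROLES = ("illumination", "sensitivity", "optical_density", "transmittance", "observer")


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling grid, in nanometres."""

    start_nm: float = 405.0
    stop_nm: float = 700.0
    step_nm: float = 5.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.stop_nm <= self.start_nm:
            raise InvalidInputError("grid requires stop > start and step > 0")
        span = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise InvalidInputError("grid span must be an integer number of steps")

    @property
    def n(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact grid point; raises if off-grid."""
        k = (wavelength_nm - self.start_nm) / self.step_nm
        if abs(k - round(k)) > 1e-9 or not 0 <= round(k) < self.n:
            raise InvalidInputError(f"{wavelength_nm} nm is not a grid point")
        return int(round(k))


#: The default 60-point visible-band grid used throughout the package.
DEFAULT_GRID = WavelengthGrid()


@dataclass(frozen=True)
class Spectrum:
    """Values sampled on a :class:`WavelengthGrid`, typed by physical role.

    ``values`` are unitless: relative intensity (illumination), relative
    sensitivity (sensor), optical density per unit relative concentration
    (stain), transmitted fraction (transmittance) or colour-matching weight
    (observer).
    """

    grid: WavelengthGrid
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.role not in ROLES:
            raise InvalidInputError(f"unknown spectrum role {self.role!r}")
        if vals.shape != (self.grid.n,):
            raise InvalidInputError(
                f"expected {self.grid.n} values for the grid, got {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("spectrum values must be finite")
        if np.any(vals < 0):
            raise InvalidInputError("spectrum values must be non-negative")
        if self.role == "transmittance" and np.any(vals > 1 + 1e-12):
            raise InvalidInputError("transmittance values must be <= 1")

    def value_at(self, wavelength_nm: float) -> float:
        return float(self.values[self.grid.index_of(wavelength_nm)])

    def with_role(self, role: str) -> "Spectrum":
        return Spectrum(self.grid, self.values.copy(), role)


def require_same_grid(*spectra: Spectrum) -> WavelengthGrid:
    grids = {s.grid for s in spectra}
    if len(grids) != 1:
        raise GridMismatchError("spectra are defined on different wavelength grids")
    return spectra[0].grid


def resample_to_grid(
    wavelengths: Sequence[float],
    values: Sequence[float],
    grid: WavelengthGrid = DEFAULT_GRID,
    role: str = "illumination",
) -> Spectrum:
    """Linearly interpolate tabulated data onto the working grid.

    Grid points outside the tabulated wavelength range are set to zero: a
    stain is treated as absorptionless and a sensor as insensitive outside
    its measured band, as when truncating a data-sheet plot.
    """
    wl = np.asarray(wavelengths, dtype=float)
    vals = np.asarray(values, dtype=float)
    if wl.ndim != 1 or wl.size < 2 or wl.shape != vals.shape:
        raise InvalidInputError("need >= 2 (wavelength, value) pairs of equal length")
    if np.any(np.diff(wl) <= 0):
        raise InvalidInputError("wavelengths must be strictly increasing")
    out = np.interp(grid.wavelengths, wl, vals, left=0.0, right=0.0)
    return Spectrum(grid, out, role)


def gaussian_band(
    peak_nm: float,
    fwhm_nm: float,
    amplitude: float = 1.0,
    grid: WavelengthGrid = DEFAULT_GRID,
    role: str = "illumination",
) -> Spectrum:
    """Gaussian emission/absorption band parameterised by peak and FWHM."""
    if fwhm_nm <= 0 or amplitude <= 0:
        raise InvalidInputError("fwhm_nm and amplitude must be positive")
    x = (grid.wavelengths - peak_nm) / fwhm_nm
    vals = amplitude * np.exp(-4.0 * math.log(2.0) * x * x)
    return Spectrum(grid, vals, role)


def gaussian_band_integral(peak_nm: float, fwhm_nm: float, amplitude: float) -> float:
    """Closed-form integral of a Gaussian band, in grid-step units of area.

    Equals ``amplitude * fwhm * sqrt(pi / (4 ln 2))``; divide by the grid
    step to compare against a plain sum over grid samples.
    """
    return amplitude * fwhm_nm * math.sqrt(math.pi / (4.0 * math.log(2.0)))


def standard_spectrum(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Embedded standard spectra: D65, uniform, CIE 1964 observer functions."""
    from . import _tables as t

    if name == "uniform":
        return Spectrum(grid, np.ones(grid.n), "illumination")
    if name == "D65":
        s = resample_to_grid(t.CIE_WAVELENGTHS_NM, t.D65_RELATIVE_POWER, grid,
                             role="illumination")
        # table is already normalised to 100 at 560 nm; renormalise defensively
        try:
            ref = s.value_at(560.0)
        except InvalidInputError:
            ref = 0.0
        vals = s.values * (100.0 / ref) if ref > 0 else s.values
        return Spectrum(grid, vals, "illumination")
    observers = {
        "CIE1964_x": t.CIE1964_XBAR,
        "CIE1964_y": t.CIE1964_YBAR,
        "CIE1964_z": t.CIE1964_ZBAR,
    }
    if name in observers:
        return resample_to_grid(t.CIE_WAVELENGTHS_NM, observers[name], grid,
                                role="observer")
    raise InvalidInputError(f"unknown standard spectrum {name!r}")


# ---------------------------------------------------------------------------
# Parametric surrogate catalogue
#
# The original measured curves behind the reference systems (vendor LED and
# CCD data sheets, measured chromogen spectra) are no longer publicly
# retrievable, so the package ships fixed parametric surrogates: sums of
# Gaussian bands whose peak positions and widths follow the published shape
# descriptions of each component.  The parameters below are version-
# controlled constants; every quantitative claim in the test-suite is made
# against these surrogates, not against the irrecoverable originals.
#
# Stain surrogates are normalised to peak optical density 1.0 at unit
# relative concentration.  LED surrogates are narrow (FWHM 20-35 nm); colour
# sensor channels are wide Bayer-filter-like bands; the monochrome sensor
# covers the whole working band.
# ---------------------------------------------------------------------------

_SURROGATE_BANDS: dict[str, tuple[str, tuple[tuple[float, float, float], ...]]] = {
    # name: (role, ((peak_nm, fwhm_nm, amplitude), ...))
    #
    # Stains: HTX (hemalum) is one broad band peaking between green and red;
    # DAB is a brown absorber rising toward blue with a long shoulder into
    # the red.  Peak positions and widths are chosen so the per-channel
    # absorbance ratios of the surrogates match published hematoxylin and
    # DAB stain vectors (H roughly (0.65, 0.70, 0.29) and DAB roughly
    # (0.27, 0.57, 0.78) in R/G/B optical density).
    "HTX": ("optical_density", ((565.0, 150.0, 1.0),)),
    "DAB": ("optical_density", ((430.0, 180.0, 1.0), (580.0, 140.0, 0.35))),
    "eosin": ("optical_density", ((525.0, 55.0, 1.0),)),
    "FastRed": ("optical_density", ((505.0, 85.0, 1.0),)),
    "MethylenGreen": ("optical_density", ((632.0, 70.0, 1.0), (420.0, 50.0, 0.20))),
    # LEDs: vendor-typical dominant wavelengths and spectral half-widths
    # for royal-blue, green and red emitters.
    "LED_R": ("illumination", ((628.0, 20.0, 1.0),)),
    "LED_G": ("illumination", ((527.0, 25.0, 1.0),)),
    "LED_B": ("illumination", ((465.0, 20.0, 1.0),)),
    # Colour sensor: wide Bayer-filter main bands plus the secondary
    # response lobes typical of dye-filter CCD channels without a sharp
    # IR-cut (the red channel responds in the blue, the green channel in
    # the far red, the blue channel weakly in the red).  This crosstalk
    # dominates the non-linear absorbance formation under wideband light.
    "sensor_R": ("sensitivity", ((620.0, 110.0, 1.0), (470.0, 125.0, 0.20))),
    "sensor_G": ("sensitivity", ((545.0, 110.0, 1.0), (695.0, 115.0, 0.40))),
    "sensor_B": ("sensitivity", ((468.0, 85.0, 1.0), (630.0, 180.0, 0.05))),
    "sensor_mono": ("sensitivity", ((530.0, 300.0, 1.0),)),
}


def surrogate_catalogue(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Fixed parametric surrogate spectra for stains, LEDs and sensors."""
    if name not in _SURROGATE_BANDS:
        raise InvalidInputError(
            f"unknown surrogate {name!r}; available: {sorted(_SURROGATE_BANDS)}"
        )
    role, bands = _SURROGATE_BANDS[name]
    total = np.zeros(grid.n)
    for peak, fwhm, amp in bands:
        total += gaussian_band(peak, fwhm, amp, grid, role=role).values
    if role == "optical_density":
        total /= total.max()  # peak OD 1.0 at unit concentration
    return Spectrum(grid, total, role)


def surrogate_names() -> tuple[str, ...]:
    return tuple(_SURROGATE_BANDS)


def read_spectrum_csv(
    path: str | Path,
    role: str,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV and resample to the grid.

    A single header row is tolerated.  Negative values and unparsable rows
    raise :class:`InvalidInputError` naming the offending row number.
    """
    wavelengths: list[float] = []
    values: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise InvalidInputError(f"{path}: row {row_no}: expected two columns")
            try:
                wl, val = float(row[0]), float(row[1])
            except ValueError:
                if row_no == 1:  # header
                    continue
                raise InvalidInputError(
                    f"{path}: row {row_no}: unparsable values {row[:2]!r}"
                ) from None
            if val < 0:
                raise InvalidInputError(f"{path}: row {row_no}: negative value {val}")
            wavelengths.append(wl)
            values.append(val)
    if len(wavelengths) < 2:
        raise InvalidInputError(f"{path}: need at least two data rows")
    return resample_to_grid(wavelengths, values, grid, role=role)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as ``wavelength_nm,value`` rows with a header."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "value"])
        for wl, val in zip(spectrum.grid.wavelengths, spectrum.values):
            writer.writerow([f"{wl:g}", repr(float(val))])
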