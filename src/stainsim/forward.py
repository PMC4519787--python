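"""Forward model of polychromatic brightfield signal formation.

A stained sample transmits the fraction ``tau(lambda) = 10**(-sum_i
delta_i(lambda) * c_i)`` of the incident light (Beer-Lambert with base-10
optical densities ``delta_i`` per unit relative concentration ``c_i``).  A
camera channel integrates this transmitted light over wavelength, weighted
by the illumination spectrum and the channel's spectral sensitivity:

    V' = sum_k I_rel(lambda_k) * s_ch(lambda_k) * tau_mix(lambda_k)

Channel absorbance is then ``A = -log10(V'/V'_0)`` against the blank signal
``V'_0`` (no stain).  Under monochromatic conditions A is exactly linear in
every concentration; under wideband conditions it is not — that
non-linearity is the methodical error this package quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InvalidInputError, SignalClippedError
from .spectra import (
    DEFAULT_GRID,
    Spectrum,
    WavelengthGrid,
    require_same_grid,
    standard_spectrum,
    surrogate_catalogue,
)


@dataclass(frozen=True)
class StainDefinition:
    """A named stain with its unit-concentration optical-density spectrum."""

    name: str
    od: Spectrum

    def __post_init__(self) -> None:
        if self.od.role != "optical_density":
            raise InvalidInputError(
                f"stain {self.name!r} requires an optical_density spectrum"
            )


def catalogue_stain(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> StainDefinition:
    """Convenience constructor for a surrogate-catalogue stain."""
    return StainDefinition(name, surrogate_catalogue(name, grid))


@dataclass(frozen=True)
class SampleComposition:
    """A mixture of stains at non-negative relative concentrations."""

    pairs: tuple[tuple[StainDefinition, float], ...]

    def __post_init__(self) -> None:
        pairs = tuple((s, float(c)) for s, c in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        for stain, c in pairs:
            if not np.isfinite(c) or c < 0:
                raise InvalidInputError(
                    f"concentration of {stain.name!r} must be finite and >= 0"
                )
        if pairs:
            require_same_grid(*(s.od for s, _ in pairs))

    @classmethod
    def of(cls, *pairs: tuple[StainDefinition, float]) -> "SampleComposition":
        return cls(tuple(pairs))

    @classmethod
    def blank(cls) -> "SampleComposition":
        return cls(())


def mixture_transmittance(
    sample: SampleComposition, grid: WavelengthGrid = DEFAULT_GRID
) -> Spectrum:
    """Spectral transmittance ``10**(-sum_i delta_i * c_i)`` of a mixture."""
    if sample.pairs:
        grid = require_same_grid(*(s.od for s, _ in sample.pairs))
    od = np.zeros(grid.n)
    for stain, c in sample.pairs:
        od += stain.od.values * c
    return Spectrum(grid, np.power(10.0, -od), "transmittance")


@dataclass(frozen=True)
class OpticalSystem:
    """Per-channel pairing of illumination and sensor sensitivity.

    A colour camera under a single lamp uses the same illumination spectrum
    in every channel with three different Bayer sensitivities.  A sequential
    LED system pairs three different narrowband illuminations with one
    monochrome sensitivity ("a colour image composed from three monochrome
    images captured sequentially").  Blank signals V'_0 per channel are
    computed once from the unstained sample and cached.
    """

    illumination: Mapping[str, Spectrum]
    sensitivity: Mapping[str, Spectrum]
    channels: tuple[str, ...] = ("R", "G", "B")
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise InvalidInputError("an optical system needs >= 2 channels")
        for ch in self.channels:
            if ch not in self.illumination or ch not in self.sensitivity:
                raise InvalidInputError(f"channel {ch!r} lacks illumination or sensor")
        require_same_grid(
            *(self.illumination[ch] for ch in self.channels),
            *(self.sensitivity[ch] for ch in self.channels),
        )
        object.__setattr__(self, "_weights", {
            ch: self.illumination[ch].values * self.sensitivity[ch].values
            for ch in self.channels
        })
        blanks = {ch: float(np.sum(self._weights[ch])) for ch in self.channels}
        for ch, v0 in blanks.items():
            if v0 <= 0:
                raise InvalidInputError(f"channel {ch!r} has zero blank signal")
        object.__setattr__(self, "blanks", blanks)

    @property
    def grid(self) -> WavelengthGrid:
        return self.illumination[self.channels[0]].grid

    def channel_weights(self, channel: str) -> np.ndarray:
        """The per-wavelength product I_rel(lambda) * s_ch(lambda)."""
        if channel not in self.channels:
            raise InvalidInputError(f"unknown channel {channel!r}")
        return self._weights[channel]


def channel_signal(
    system: OpticalSystem, sample: SampleComposition, channel: str
) -> float:
    """Polychromatic camera signal V' of one channel for a stain mixture."""
    weights = system.channel_weights(channel)
    tau = mixture_transmittance(sample, system.grid)
    require_same_grid(tau, system.illumination[channel])
    return float(np.sum(weights * tau.values))


def channel_absorbance(v: float, v0: float, clamp_lsb: float | None = None) -> float:
    """Channel absorbance ``A = -log10(V/V0)`` against the blank signal V0.

    The forward model itself never produces V <= 0; quantised or imported
    signals can, in which case ``clamp_lsb`` (e.g. 0.5 for 8-bit data on a
    0..255 scale) clamps the signal before taking the logarithm.  V > V0
    yields a negative absorbance and a warning, never an exception.
    """
    if v0 <= 0:
        raise InvalidInputError("blank signal V0 must be positive")
    if v <= 0:
        if clamp_lsb is None:
            raise SignalClippedError(
                f"signal {v} <= 0 has no absorbance; pass clamp_lsb to clamp"
            )
        v = clamp_lsb
    if v > v0:
        warnings.warn(
            f"signal {v} exceeds blank {v0}; returning negative absorbance",
            stacklevel=2,
        )
    return float(-np.log10(v / v0))


def sample_absorbance_vector(
    system: OpticalSystem, sample: SampleComposition
) -> np.ndarray:
    """Per-channel absorbance of a mixture, ordered like ``system.channels``."""
    return np.array([
        channel_absorbance(channel_signal(system, sample, ch), system.blanks[ch])
        for ch in system.channels
    ])


def render_xyz(
    illumination: Spectrum, sample: SampleComposition
) -> tuple[float, float, float]:
    """CIE 1964 XYZ tristimulus of the transmitted light, blank Y = 100.

    Used to validate that simulated transmittance spectra produce plausible
    stain colours; plain spectral summation against the embedded observer.
    """
    grid = illumination.grid
    xbar = standard_spectrum("CIE1964_x", grid).values
    ybar = standard_spectrum("CIE1964_y", grid).values
    zbar = standard_spectrum("CIE1964_z", grid).values
    tau = mixture_transmittance(sample, grid)
    require_same_grid(illumination, tau)
    k = 100.0 / float(np.sum(illumination.values * ybar))
    light = illumination.values * tau.values
    return (
        k * float(np.sum(light * xbar)),
        k * float(np.sum(light * ybar)),
        k * float(np.sum(light * zbar)),
    )


# ---------------------------------------------------------------------------
# Reference system builders
# ---------------------------------------------------------------------------

def wideband_system(
    illuminant: str = "D65", grid: WavelengthGrid = DEFAULT_GRID
) -> OpticalSystem:
    """Wideband illumination plus a colour-camera sensor surrogate."""
    light = standard_spectrum(illuminant, grid)
    return OpticalSystem(
        illumination={ch: light for ch in "RGB"},
        sensitivity={ch: surrogate_catalogue(f"sensor_{ch}", grid) for ch in "RGB"},
        name=f"{illuminant}/colour-sensor",
    )


def sequential_led_system(grid: WavelengthGrid = DEFAULT_GRID) -> OpticalSystem:
    """Sequential narrowband RGB LEDs plus a monochrome sensor surrogate."""
    mono = surrogate_catalogue("sensor_mono", grid)
    return OpticalSystem(
        illumination={ch: surrogate_catalogue(f"LED_{ch}", grid) for ch in "RGB"},
        sensitivity={ch: mono for ch in "RGB"},
        name="RGB-LED/monochrome-sensor",
    )


def monochromatic_system(
    wavelengths_nm: Mapping[str, float] | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> OpticalSystem:
    """Idealised system sensing exactly one wavelength per channel.

    With single-wavelength channels the absorbance vector is exactly linear
    in every stain concentration, making this the ground-truth reference for
    every identity check in the package.
    """
    if wavelengths_nm is None:
        wavelengths_nm = {"R": 630.0, "G": 530.0, "B": 465.0}
    illumination = {}
    for ch, wl in wavelengths_nm.items():
        vals = np.zeros(grid.n)
        vals[grid.index_of(wl)] = 1.0
        illumination[ch] = Spectrum(grid, vals, "illumination")
    ones = Spectrum(grid, np.ones(grid.n), "sensitivity")
    return OpticalSystem(
        illumination=illumination,
        sensitivity={ch: ones for ch in wavelengths_nm},
        channels=tuple(wavelengths_nm),
        name="monochromatic",
    )
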