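"""Deconvolution error surfaces, summary statistics and error-map correction.

For a two-stain mixture the workflow mirrors a calibrated measurement: pure
stain vectors are measured at a reference concentration, normalised, and
used to unmix simulated absorbances of every concentration combination on a
grid.  The relative error ``(c*_out - c*_in) / c*_in`` per stain and grid
cell forms an error surface.  Because every error is a deterministic
aberrance of the linear unmixing of non-linear signals — not a statistical
fluctuation — the same surface, computed on a refined grid, can be inverted
to correct measurements taken under identical spectral conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ExtrapolationError, InvalidInputError
from .forward import OpticalSystem, SampleComposition, StainDefinition, \
    sample_absorbance_vector
from .unmix import StainMatrix, measure_stain_vector, unmix_exact

#: Concentration grid used for the headline error surfaces.
DEFAULT_GRID_VALUES = (0.1, 1.0, 2.0, 4.0, 8.0)

#: Channel plane used for two-stain exact unmixing.
DEFAULT_CHANNELS = ("B", "G")


def relative_error(c_out: float, c_in: float) -> float:
    """Relative deconvolution error ``(c_out - c_in) / c_in``.

    Undefined at ``c_in = 0``; returns NaN as an explicit undefined flag so
    grid constructions stay array-shaped without inventing a number.
    """
    if c_in == 0:
        return math.nan
    return (c_out - c_in) / c_in


@dataclass(frozen=True)
class ErrorSurface:
    """Input/output concentration grids with relative errors per stain.

    ``c_out[s, i, j]`` and ``delta[s, i, j]`` refer to stain ``s`` at input
    cell ``(grid_values[i], grid_values[j])`` where axis 0 of the cell index
    is the first stain's input and axis 1 the second's.  Concentrations are
    normalised (c*), i.e. relative to unit-length stain vectors; ``vector_
    norms`` convert back to relative concentrations c' = c*/||q||.
    """

    stain_names: tuple[str, str]
    channels: tuple[str, ...]
    grid_values: np.ndarray
    c_out: np.ndarray
    delta: np.ndarray
    vector_norms: tuple[float, float]
    system_name: str = ""

    def __post_init__(self) -> None:
        n = len(self.grid_values)
        if self.c_out.shape != (2, n, n) or self.delta.shape != (2, n, n):
            raise InvalidInputError("surface layers must be shaped (2, n, n)")

    @property
    def c_in(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast input grids (first stain varies along axis 0)."""
        g = np.asarray(self.grid_values, dtype=float)
        return np.meshgrid(g, g, indexing="ij")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: c_in1, c_in2, c_out1, c_out2, dc1, dc2."""
        c1, c2 = self.c_in
        return pd.DataFrame({
            "c_in1": c1.ravel(),
            "c_in2": c2.ravel(),
            "c_out1": self.c_out[0].ravel(),
            "c_out2": self.c_out[1].ravel(),
            "dc1": self.delta[0].ravel(),
            "dc2": self.delta[1].ravel(),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def error_surface(
    system: OpticalSystem,
    stains: Sequence[StainDefinition],
    grid_values: Sequence[float] = DEFAULT_GRID_VALUES,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    reference_c: float = 1.0,
) -> ErrorSurface:
    """Simulate, absorb and unmix every concentration pair on a grid.

    Stain vectors are measured at ``reference_c`` (default: relative
    concentration 1) under the same system, projected onto ``channels``
    and normalised; inputs and outputs are normalised concentrations c*
    with respect to those unit vectors.
    """
    if len(stains) != 2:
        raise InvalidInputError("error surfaces are defined for stain pairs")
    grid_values = np.asarray(sorted(grid_values), dtype=float)
    if np.any(grid_values < 0) or len(grid_values) < 1:
        raise InvalidInputError("grid values must be non-negative")

    channels = tuple(channels)
    idx = [system.channels.index(ch) for ch in channels]
    raw = [measure_stain_vector(system, s, reference_c).project(channels)
           for s in stains]
    norms = tuple(v.norm for v in raw)
    matrix = StainMatrix.from_vectors([v.normalise() for v in raw], channels)

    n = len(grid_values)
    c_out = np.empty((2, n, n))
    delta = np.empty((2, n, n))
    for i, c1 in enumerate(grid_values):
        for j, c2 in enumerate(grid_values):
            sample = SampleComposition.of(
                (stains[0], c1 / norms[0]), (stains[1], c2 / norms[1])
            )
            a = sample_absorbance_vector(system, sample)[idx]
            out = unmix_exact(matrix, a)
            c_out[:, i, j] = out
            delta[0, i, j] = relative_error(out[0], c1)
            delta[1, i, j] = relative_error(out[1], c2)
    return ErrorSurface(
        stain_names=(stains[0].name, stains[1].name),
        channels=channels,
        grid_values=grid_values,
        c_out=c_out,
        delta=delta,
        vector_norms=norms,
        system_name=system.name,
    )


def _retained_mask(surface: ErrorSurface, min_c_in: float) -> np.ndarray:
    c1, c2 = surface.c_in
    return (c1 >= min_c_in) & (c2 >= min_c_in)


def average_abs_error(
    surface: ErrorSurface, min_c_in: float = 1.0, pooled: bool = False
):
    """Mean |relative error| over cells where both inputs >= ``min_c_in``.

    Small input concentrations make the relative error blow up through its
    denominator and would dominate any average, so cells below the threshold
    are excluded.  Returns a per-stain dict, or a single pooled mean over
    both stains' retained values when ``pooled`` is true.
    """
    mask = _retained_mask(surface, min_c_in)
    if not mask.any():
        raise InvalidInputError("no grid cells retained by the exclusion rule")
    per_stain = {
        name: float(np.nanmean(np.abs(surface.delta[s][mask])))
        for s, name in enumerate(surface.stain_names)
    }
    if pooled:
        return float(np.nanmean(np.abs(
            np.stack([surface.delta[0][mask], surface.delta[1][mask]])
        )))
    return per_stain


@dataclass(frozen=True)
class SystemComparison:
    """Error ratios between two optical systems for one stain pair."""

    per_stain: dict[str, float]
    pooled: float
    infinite: bool
    errors_a: dict[str, float]
    errors_b: dict[str, float]


def compare_systems(
    system_a: OpticalSystem,
    system_b: OpticalSystem,
    stains: Sequence[StainDefinition],
    grid_values: Sequence[float] = DEFAULT_GRID_VALUES,
    channels: Sequence[str] = DEFAULT_CHANNELS,
    min_c_in: float = 1.0,
) -> SystemComparison:
    """Ratio of average absolute errors (A over B), per stain and pooled.

    A vanishing denominator (a monochromatic reference system, whose mean
    error is zero up to round-off) is reported as infinity with the
    ``infinite`` flag set, never an exception.
    """
    surf_a = error_surface(system_a, stains, grid_values, channels)
    surf_b = error_surface(system_b, stains, grid_values, channels)
    err_a = average_abs_error(surf_a, min_c_in)
    err_b = average_abs_error(surf_b, min_c_in)
    zero = 1e-12  # below this a mean |relative error| is numerically zero
    per_stain = {}
    infinite = False
    for name in err_a:
        if err_b[name] < zero:
            per_stain[name] = math.inf
            infinite = True
        else:
            per_stain[name] = err_a[name] / err_b[name]
    pooled_a = average_abs_error(surf_a, min_c_in, pooled=True)
    pooled_b = average_abs_error(surf_b, min_c_in, pooled=True)
    if pooled_b < zero:
        pooled = math.inf
        infinite = True
    else:
        pooled = pooled_a / pooled_b
    return SystemComparison(per_stain, pooled, infinite, err_a, err_b)


def error_map_correct(
    surface: ErrorSurface, measured_c_out: Sequence[float]
) -> np.ndarray:
    """Invert the input-to-output map of a surface at a measured output pair.

    The forward map c*_in -> c*_out sampled by the surface is smooth in the
    inputs, so it is spline-interpolated on the surface's regular input grid
    and inverted by bounded least squares, started from the grid node whose
    simulated output lies closest to the measurement.  The surface should be
    computed on a refined grid (step around 0.25 in c*) so interpolation
    error stays below the deconvolution error being corrected.  A
    measurement that no input inside the calibrated grid can produce is
    refused rather than extrapolated.
    """
    from scipy.interpolate import RectBivariateSpline
    from scipy.optimize import least_squares

    measured = np.asarray(measured_c_out, dtype=float)
    if measured.shape != (2,):
        raise InvalidInputError("measured_c_out must be a pair")
    g = np.asarray(surface.grid_values, dtype=float)
    if len(g) < 2:
        raise InvalidInputError("error-map correction needs a 2-D surface grid")
    k = min(3, len(g) - 1)
    splines = [RectBivariateSpline(g, g, surface.c_out[s], kx=k, ky=k)
               for s in range(2)]

    def forward(c: np.ndarray) -> np.ndarray:
        return np.array([sp(c[0], c[1], grid=False).item() for sp in splines])

    # start from the node with the closest simulated output
    outputs = np.column_stack([surface.c_out[0].ravel(), surface.c_out[1].ravel()])
    c1, c2 = surface.c_in
    nearest = np.argmin(np.sum((outputs - measured) ** 2, axis=1))
    x0 = np.array([c1.ravel()[nearest], c2.ravel()[nearest]])
    fit = least_squares(lambda c: forward(c) - measured, x0,
                        bounds=(g[0], g[-1]), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    scale = max(1.0, float(np.linalg.norm(measured)))
    if np.linalg.norm(fit.fun) > 1e-6 * scale:
        raise ExtrapolationError(
            f"measured output {measured.tolist()} is not reachable from the "
            "calibrated input region of this error map"
        )
    return fit.x


def refined_surface(
    system: OpticalSystem,
    stains: Sequence[StainDefinition],
    c_min: float = 0.25,
    c_max: float = 8.0,
    step: float = 0.25,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> ErrorSurface:
    """Error surface on a dense grid, suitable for error-map correction."""
    grid_values = np.arange(c_min, c_max + step / 2, step)
    return error_surface(system, stains, grid_values, channels)
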