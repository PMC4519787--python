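"""Synthetic scenes, pixel-wise rendering and cell quantification.

Closes the loop from known ground truth to measured biology: concentration
images with exactly known per-pixel stain concentrations are rendered to
RGB camera images through the forward model, deconvolved pixel-wise back to
concentration images, and both are pushed through the same threshold-based
cell detection so the propagation of the deconvolution error into object
counts, areas and mean concentrations can be quantified directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_isodata, threshold_otsu, threshold_yen

from .errors import InvalidInputError, NoThresholdError, SignalClippedError
from .forward import OpticalSystem, StainDefinition
from .unmix import StainMatrix, unmix_exact, unmix_lsq

#: 8-connected neighbourhood, the particle-analysis convention.
_CONNECTIVITY_8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ConcentrationImage:
    """One non-negative floating-point concentration plane per stain."""

    planes: np.ndarray  # (n_stains, height, width)
    stain_names: tuple[str, ...]

    def __post_init__(self) -> None:
        planes = np.asarray(self.planes, dtype=float)
        object.__setattr__(self, "planes", planes)
        if planes.ndim != 3 or planes.shape[0] != len(self.stain_names):
            raise InvalidInputError("planes must be shaped (n_stains, H, W)")
        if not np.all(np.isfinite(planes)):
            raise InvalidInputError("concentrations must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def plane(self, stain: str) -> np.ndarray:
        return self.planes[self.stain_names.index(stain)]

    def to_tiff(self, path: str | Path) -> None:
        """Write as a multi-page 32-bit float TIFF, one page per stain."""
        tifffile.imwrite(path, self.planes.astype(np.float32))

    @classmethod
    def from_tiff(cls, path: str | Path,
                  stain_names: Sequence[str]) -> "ConcentrationImage":
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        return cls(data, tuple(stain_names))


@dataclass(frozen=True)
class RGBImage:
    """Rendered camera image: real-valued signals or 8-bit quantised values."""

    data: np.ndarray  # (height, width, n_channels)
    channels: tuple[str, ...]
    quantised: bool

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channels):
            raise InvalidInputError("data must be shaped (H, W, n_channels)")
        if self.quantised:
            if self.data.min() < 0 or self.data.max() > 255:
                raise InvalidInputError("8-bit values must lie in [0, 255]")

    def to_png(self, path: str | Path) -> None:
        if not self.quantised:
            raise InvalidInputError("only quantised images can be written as PNG")
        iio.imwrite(path, self.data.astype(np.uint8))


def make_cell_scene(
    width: int,
    height: int,
    n_cells: int,
    c_range: Sequence[tuple[float, float]] = ((0.5, 4.0), (0.5, 4.0)),
    seed: int = 0,
    stain_names: tuple[str, ...] = ("DAB", "HTX"),
) -> ConcentrationImage:
    """Seeded scene of soft-edged elliptical cells mimicking a stained sample.

    Each cell is an ellipse with random centre, semi-axes and orientation;
    its peak concentration for every stain is drawn uniformly from that
    stain's ``c_range``.  The profile is flat in the core with a linear
    soft rim, and overlapping cells combine by per-pixel maximum.  Identical
    seeds reproduce identical scenes.
    """
    if width < 8 or height < 8:
        raise InvalidInputError("scene must be at least 8x8 pixels")
    if n_cells < 1:
        raise InvalidInputError("need at least one cell")
    if len(c_range) != len(stain_names):
        raise InvalidInputError("one concentration range per stain required")
    rng = np.random.default_rng(seed)
    planes = np.zeros((len(stain_names), height, width))
    yy, xx = np.mgrid[0:height, 0:width]
    r_lo, r_hi = 0.05 * min(width, height), 0.12 * min(width, height)
    for _ in range(n_cells):
        a, b = rng.uniform(r_lo, r_hi, size=2)
        margin = max(a, b) + 1
        cx = rng.uniform(margin, width - margin)
        cy = rng.uniform(margin, height - margin)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = ((xx - cx) * ct + (yy - cy) * st) / a
        v = (-(xx - cx) * st + (yy - cy) * ct) / b
        r = np.sqrt(u * u + v * v)
        profile = np.clip((1.0 - r) / 0.25, 0.0, 1.0)  # soft 25% rim
        for s, (lo, hi) in enumerate(c_range):
            peak = rng.uniform(lo, hi)
            planes[s] = np.maximum(planes[s], peak * profile)
    return ConcentrationImage(planes, stain_names)


def make_selfsimilar_scene(
    levels: int,
    c_values: Sequence[float],
    tile_px: int = 40,
    stain_names: tuple[str, str] = ("DAB", "HTX"),
) -> ConcentrationImage:
    """Nested-square test pattern with exactly known concentration values.

    The canvas is an n x n grid of flat squares (n = number of c values);
    tile (i, j) carries the first stain at ``c_values[i]``.  Each further
    level inserts a centred square of half the previous side carrying the
    other stain (alternating), cycling through ``c_values``.  Every pixel's
    ground-truth pair is therefore drawn from the requested values plus 0,
    and the regions where only the first stain is present (outside the
    insets) are exact pure-stain patches.
    """
    if levels < 1:
        raise InvalidInputError("need at least one level")
    n = len(c_values)
    if n < 1:
        raise InvalidInputError("need at least one concentration value")
    if tile_px // 2 ** (levels - 1) < 2:
        raise InvalidInputError("too many levels for this tile size")
    size = n * tile_px
    planes = np.zeros((2, size, size))
    for i in range(n):
        for j in range(n):
            y0, x0 = i * tile_px, j * tile_px
            side = tile_px
            cy, cx = y0 + tile_px // 2, x0 + tile_px // 2
            for level in range(levels):
                half = side // 2
                ys, xs = cy - half, cx - half
                stain = level % 2
                value = c_values[(i, j, i + j + level)[min(level, 2)] % n]
                planes[stain, ys:ys + side, xs:xs + side] = value
                side //= 2
    return ConcentrationImage(planes, stain_names)


def render_rgb(
    system: OpticalSystem,
    scene: ConcentrationImage,
    stains: Sequence[StainDefinition],
    quantise: bool = False,
) -> RGBImage:
    """Render a concentration image to camera signals, pixel by pixel.

    With ``quantise`` the signals are scaled so the blank maps to 255 per
    channel and rounded half-up to integers, emulating an 8-bit camera.
    """
    names = tuple(s.name for s in stains)
    if names != scene.stain_names:
        raise InvalidInputError(
            f"scene stains {scene.stain_names} do not match system stain set {names}"
        )
    od_spectra = np.stack([s.od.values for s in stains])  # (S, L)
    od_total = np.einsum("shw,sl->hwl", scene.planes, od_spectra)
    tau = np.power(10.0, -od_total)  # (H, W, L)
    signals = np.stack(
        [tau @ system.channel_weights(ch) for ch in system.channels], axis=-1
    )
    if not quantise:
        return RGBImage(signals, system.channels, quantised=False)
    blanks = np.array([system.blanks[ch] for ch in system.channels])
    quantised = np.floor(signals / blanks * 255.0 + 0.5).clip(0, 255)
    return RGBImage(quantised.astype(np.uint8), system.channels, quantised=True)


@dataclass(frozen=True)
class DeconvolutionResult:
    """Pixel-wise unmixing output with optional ground-truth comparison."""

    c_out: ConcentrationImage
    difference: ConcentrationImage | None  # c_in - c_out, None without truth
    max_abs_relative_error: dict[str, float] | None


def deconvolve_image(
    rgb: RGBImage,
    system: OpticalSystem,
    stain_matrix: StainMatrix,
    solver: str = "lsq",
    ground_truth: ConcentrationImage | None = None,
    clamp_lsb: float = 0.5,
) -> DeconvolutionResult:
    """Deconvolve a rendered image back into concentration planes.

    Signals are converted to per-channel absorbances against the system
    blanks and unmixed per pixel, either exactly (square matrix after
    channel projection) or by QR least squares on all channels.  Quantised
    images are de-quantised with a half-LSB clamp so zero pixels stay
    finite.  Output planes may contain negative values; they are reported,
    never clipped.
    """
    if solver not in ("exact", "lsq"):
        raise InvalidInputError("solver must be 'exact' or 'lsq'")
    blanks = np.array([system.blanks[ch] for ch in rgb.channels])
    if rgb.quantised:
        v = np.maximum(rgb.data.astype(float), clamp_lsb) / 255.0 * blanks
    else:
        v = rgb.data.astype(float)
        if np.any(v <= 0):
            raise SignalClippedError(
                "zero or negative signal pixels; quantised data would be clamped"
            )
    absorbance = -np.log10(v / blanks)  # (H, W, C)

    matrix = stain_matrix.project(rgb.channels) \
        if solver == "lsq" else stain_matrix
    idx = [rgb.channels.index(ch) for ch in matrix.channels]
    h, w = absorbance.shape[:2]
    a_flat = absorbance[..., idx].reshape(-1, len(idx)).T  # (C_used, N)
    if solver == "exact":
        c_flat = unmix_exact(matrix, a_flat)
    else:
        c_flat = unmix_lsq(matrix, a_flat)
    planes = c_flat.reshape(len(matrix.stain_names), h, w)
    # negative outputs are legitimate results; bypass the >= 0 construction
    c_out = object.__new__(ConcentrationImage)
    object.__setattr__(c_out, "planes", planes)
    object.__setattr__(c_out, "stain_names", matrix.stain_names)

    if ground_truth is None:
        return DeconvolutionResult(c_out, None, None)
    if ground_truth.stain_names != matrix.stain_names:
        raise InvalidInputError("ground truth stain names do not match the matrix")
    diff_planes = ground_truth.planes - planes
    difference = object.__new__(ConcentrationImage)
    object.__setattr__(difference, "planes", diff_planes)
    object.__setattr__(difference, "stain_names", matrix.stain_names)
    max_err = {}
    for s, name in enumerate(matrix.stain_names):
        mask = ground_truth.planes[s] > 0
        if mask.any():
            rel = np.abs(diff_planes[s][mask] / ground_truth.planes[s][mask])
            max_err[name] = float(rel.max())
        else:
            max_err[name] = 0.0
    return DeconvolutionResult(c_out, difference, max_err)


def rescale_to_8bit(
    plane: np.ndarray, display_min: float, display_max: float
) -> np.ndarray:
    """Linear map of a float plane to 0..255 with clipping, rounded half-up."""
    if display_max <= display_min:
        raise InvalidInputError("display_max must exceed display_min")
    scaled = (np.asarray(plane, dtype=float) - display_min) \
        / (display_max - display_min) * 255.0
    return np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)


def threshold(plane: np.ndarray, method: str = "default") -> np.ndarray:
    """Automatic threshold of an 8-bit plane; foreground is above threshold.

    ``default`` is the iterative isodata mean-split (the basis of ImageJ's
    Default mode), ``otsu`` maximises between-class variance, ``yen``
    maximises Yen's entropic criterion.
    """
    plane = np.asarray(plane)
    if plane.min() == plane.max():
        raise NoThresholdError("constant plane has no threshold")
    methods = {"default": threshold_isodata, "otsu": threshold_otsu,
               "yen": threshold_yen}
    if method not in methods:
        raise InvalidInputError(f"unknown threshold method {method!r}")
    t = methods[method](plane)
    return plane > t


@dataclass(frozen=True)
class CellMeasurements:
    """Object count, per-object area and mean concentration, and pixel mean."""

    count: int
    areas: np.ndarray  # pixels per object
    mean_concentrations: np.ndarray  # per object
    pixel_mean: float  # mean concentration over the whole mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "object_id": np.arange(1, self.count + 1),
            "area_px": self.areas.astype(int),
            "mean_concentration": self.mean_concentrations,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def label_and_measure(mask: np.ndarray, plane: np.ndarray) -> CellMeasurements:
    """Label 8-connected components and measure them on a concentration plane."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != plane.shape:
        raise InvalidInputError("mask and plane shapes differ")
    labels, count = ndimage.label(mask, structure=_CONNECTIVITY_8)
    if count == 0:
        return CellMeasurements(0, np.array([]), np.array([]), 0.0)
    ids = np.arange(1, count + 1)
    areas = ndimage.sum_labels(mask, labels, ids)
    means = ndimage.mean(plane, labels, ids)
    pixel_mean = float(plane[mask].mean())
    return CellMeasurements(int(count), np.asarray(areas),
                            np.asarray(means), pixel_mean)
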