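"""Stain vectors and linear colour deconvolution.

A stain vector collects the per-channel absorbances of a pure stain; the
stain vectors of all stains in a mixture form the coefficient matrix of the
linear unmixing system ``M c = a``.  Because polychromatic absorbance is not
linear in concentration, stain vectors measured at different concentrations
point in (slightly) different directions; the average angle variation (AAV)
quantifies that spread and serves as a reliability criterion for a stain
vector under given spectral conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .errors import CollinearStainsError, DegenerateInputError, InvalidInputError
from .forward import (
    OpticalSystem,
    SampleComposition,
    StainDefinition,
    sample_absorbance_vector,
)

#: Condition number above which a stain matrix is treated as collinear.
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class StainVector:
    """Per-channel absorbance signature of a pure stain."""

    stain: str
    components: np.ndarray
    channels: tuple[str, ...]
    normalised: bool = False
    source_concentration: float = 1.0

    def __post_init__(self) -> None:
        comps = np.asarray(self.components, dtype=float)
        object.__setattr__(self, "components", comps)
        if comps.shape != (len(self.channels),):
            raise InvalidInputError("one component per channel required")
        if not np.all(np.isfinite(comps)):
            raise InvalidInputError("stain vector components must be finite")
        if self.normalised and abs(np.linalg.norm(comps) - 1.0) > 1e-9:
            raise InvalidInputError("normalised stain vector must have unit length")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.components))

    def normalise(self) -> "StainVector":
        n = self.norm
        if n == 0:
            raise DegenerateInputError(f"stain vector {self.stain!r} is zero")
        return replace(self, components=self.components / n, normalised=True)

    def project(self, channels: Sequence[str]) -> "StainVector":
        """Restrict to a channel subset (e.g. the B/G plane); drops the
        normalised flag since projection changes the length."""
        idx = [self.channels.index(ch) for ch in channels]
        return StainVector(
            self.stain, self.components[idx], tuple(channels),
            normalised=False, source_concentration=self.source_concentration,
        )


def measure_stain_vector(
    system: OpticalSystem,
    stain: StainDefinition,
    c: float,
    normalise: bool = False,
) -> StainVector:
    """Stain vector of a pure stain at concentration ``c`` under a system."""
    if c <= 0:
        raise InvalidInputError("stain vector concentration must be positive")
    components = sample_absorbance_vector(system, SampleComposition.of((stain, c)))
    vec = StainVector(stain.name, components, system.channels,
                      source_concentration=c)
    return vec.normalise() if normalise else vec


def stain_vector_sweep(
    system: OpticalSystem,
    stain: StainDefinition,
    concentrations: Sequence[float] = (1, 2, 3, 4, 5),
    normalise: bool = True,
) -> list[StainVector]:
    """Stain vectors of one stain over a range of concentrations."""
    return [measure_stain_vector(system, stain, c, normalise) for c in concentrations]


def average_angle_variation(vectors: Sequence[StainVector]) -> float:
    """Mean angle (degrees) between each vector and their normalised mean.

    Zero under monochromatic conditions, where all vectors share one
    direction regardless of the concentration they were measured at.
    """
    if len(vectors) < 2:
        raise InvalidInputError("AAV needs at least two stain vectors")
    channels = vectors[0].channels
    for v in vectors:
        if not v.normalised:
            raise InvalidInputError("AAV is defined on normalised vectors")
        if v.channels != channels:
            raise InvalidInputError("AAV vectors must share one channel space")
    mean = np.mean([v.components for v in vectors], axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-300:
        raise DegenerateInputError("mean stain vector is zero")
    mean /= norm
    # chord-based angle (2 arcsin of half the chord) stays accurate for the
    # near-zero angles of quasi-monochromatic systems, unlike arccos of a dot
    # product, which loses half the significant digits near 1
    angles = [
        np.degrees(2.0 * np.arcsin(
            min(1.0, 0.5 * float(np.linalg.norm(v.components - mean)))))
        for v in vectors
    ]
    return float(np.mean(angles))


@dataclass(frozen=True)
class StainMatrix:
    """Ordered stain vectors forming the deconvolution coefficient matrix."""

    vectors: tuple[StainVector, ...]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        vecs = tuple(v.project(self.channels) if v.channels != self.channels else v
                     for v in self.vectors)
        object.__setattr__(self, "vectors", vecs)
        if len(vecs) == 0:
            raise InvalidInputError("a stain matrix needs at least one stain")
        if len(self.channels) < len(vecs):
            raise InvalidInputError(
                "need at least as many channels as stains for solvability"
            )

    @classmethod
    def from_vectors(cls, vectors: Sequence[StainVector],
                     channels: Sequence[str] | None = None) -> "StainMatrix":
        chans = tuple(channels) if channels is not None else vectors[0].channels
        return cls(tuple(vectors), chans)

    @property
    def matrix(self) -> np.ndarray:
        """Channels x stains coefficient matrix (stain vectors as columns)."""
        return np.column_stack([v.components for v in self.vectors])

    @property
    def stain_names(self) -> tuple[str, ...]:
        return tuple(v.stain for v in self.vectors)

    def project(self, channels: Sequence[str]) -> "StainMatrix":
        return StainMatrix(self.vectors, tuple(channels))

    def to_csv(self, path: str | Path) -> None:
        """Serialise as CSV with stains as columns and channels as rows."""
        pd.DataFrame(self.matrix, index=list(self.channels),
                     columns=list(self.stain_names)).to_csv(path, index_label="channel")

    @classmethod
    def read_csv(cls, path: str | Path) -> "StainMatrix":
        df = pd.read_csv(path, index_col=0)
        channels = tuple(df.index)
        vectors = tuple(
            StainVector(name, df[name].to_numpy(float), channels)
            for name in df.columns
        )
        return cls(vectors, channels)


def unmix_exact(matrix: StainMatrix, a: np.ndarray) -> np.ndarray:
    """Solve the square unmixing system exactly.

    Concentrations may legitimately come out negative: absorbance vectors of
    non-linearly formed signals can fall outside the fan spanned by the
    stain vectors, and clipping would hide exactly that effect.
    """
    m = matrix.matrix
    if m.shape[0] != m.shape[1]:
        raise InvalidInputError(
            f"exact unmixing needs a square matrix, got {m.shape}; "
            "project onto a channel subset first"
        )
    if np.linalg.cond(m) > CONDITION_LIMIT:
        raise CollinearStainsError("stain vectors are (near-)collinear")
    a = np.asarray(a, dtype=float)
    if a.shape[0] != m.shape[0]:
        raise InvalidInputError("absorbance vector length must match channels")
    return np.linalg.solve(m, a)


def unmix_lsq(matrix: StainMatrix, a: np.ndarray) -> np.ndarray:
    """Least-squares unmixing of an over-determined system via QR.

    ``M = Q R`` with orthonormal Q; the minimiser of ``||M c - a||`` is
    ``c = R^-1 Q^T a``.  Used for 3-channel unmixing of two stains.
    """
    m = matrix.matrix
    a = np.asarray(a, dtype=float)
    if a.shape[0] != m.shape[0]:
        raise InvalidInputError("absorbance vector length must match channels")
    q, r = np.linalg.qr(m)
    diag = np.abs(np.diag(r))
    if diag.min() <= diag.max() / CONDITION_LIMIT or diag.max() == 0:
        raise CollinearStainsError("stain matrix is rank deficient")
    rhs = q.T @ a
    if a.ndim == 1:
        return solve_triangular(r, rhs)
    return solve_triangular(r, rhs)


def denormalise_concentration(c_star: float, q_length: float) -> float:
    """Convert a normalised concentration c* into a relative one c'.

    Unmixing with unit-length stain vectors yields c* = ||q|| * c', so the
    relative concentration is c' = c* / ||q||.
    """
    if q_length <= 0:
        raise InvalidInputError("stain vector length must be positive")
    return c_star / q_length


def normalise_concentration(c_prime: float, q_length: float) -> float:
    """Forward relation c* = ||q|| * c' (inverse of denormalisation)."""
    if q_length <= 0:
        raise InvalidInputError("stain vector length must be positive")
    return c_prime * q_length
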