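"""Core spatial containers: scalar volumes, velocity fields and deformations.

All fields live on a regular 3-D grid. Vector quantities (velocities,
displacements) are expressed in *voxel* units along the array axes; world
spacing and origin are carried for I/O and metric computations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Image3D",
    "VelocityField",
    "Diffeo",
    "LabelMap3D",
    "InvalidInputError",
    "IncompatibleGridError",
]


class InvalidInputError(ValueError):
    """Raised when a field violates its contract (non-finite values, empty grid ...)."""


class IncompatibleGridError(ValueError):
    """Raised when two objects that must share a grid do not."""


def _as_triplet(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape == ():
        arr = np.full(3, float(arr))
    if arr.shape != (3,):
        raise InvalidInputError(f"{name} must be a scalar or length-3 sequence, got shape {arr.shape}")
    return arr


@dataclass
class Image3D:
    """A scalar volume on a regular grid.

    Parameters
    ----------
    values : (X, Y, Z) float array
        Intensities, arbitrary units.
    spacing : length-3 sequence, mm per voxel along each axis.
    origin : length-3 sequence, world position of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise InvalidInputError(f"Image3D requires a non-empty 3-D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("Image3D values must be finite")
        self.spacing = _as_triplet(self.spacing, "spacing")
        self.origin = _as_triplet(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise InvalidInputError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def copy(self) -> "Image3D":
        return Image3D(self.values.copy(), self.spacing.copy(), self.origin.copy())


@dataclass
class LabelMap3D:
    """An integer-coded segmentation on a regular grid.

    ``key`` optionally maps label id -> structure name.
    """

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    key: Optional[dict] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = np.rint(self.labels).astype(np.int32)
            if not np.allclose(self.labels, as_int):
                raise InvalidInputError("LabelMap3D requires integer labels")
            self.labels = as_int
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise InvalidInputError(f"LabelMap3D requires a non-empty 3-D array, got {self.labels.shape}")
        self.spacing = _as_triplet(self.spacing, "spacing")
        self.origin = _as_triplet(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise InvalidInputError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        return np.unique(self.labels)

    def copy(self) -> "LabelMap3D":
        return LabelMap3D(self.labels.copy(), self.spacing.copy(), self.origin.copy(),
                          dict(self.key) if self.key else None)


@dataclass
class VelocityField:
    """A stationary velocity field (SVF): the Lie-algebra representation of a
    diffeomorphism. ``vectors`` has shape (X, Y, Z, 3) in voxel units; the zero
    field represents the identity map."""

    vectors: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3 or self.vectors[..., 0].size == 0:
            raise InvalidInputError(
                f"VelocityField requires a non-empty (X, Y, Z, 3) array, got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise InvalidInputError("VelocityField must be finite")
        self.spacing = _as_triplet(self.spacing, "spacing")
        self.origin = _as_triplet(self.origin, "origin")
        if np.any(self.spacing <= 0):
            raise InvalidInputError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.vectors.shape[:3]

    def max_norm(self) -> float:
        """Largest per-voxel Euclidean magnitude (voxels)."""
        return float(np.sqrt((self.vectors ** 2).sum(axis=-1)).max())

    def copy(self) -> "VelocityField":
        return VelocityField(self.vectors.copy(), self.spacing.copy(), self.origin.copy())

    def __neg__(self) -> "VelocityField":
        return VelocityField(-self.vectors, self.spacing.copy(), self.origin.copy())


@dataclass
class Diffeo:
    """A dense diffeomorphic map x -> x + displacement(x), in voxel units.

    When the map was produced by exponentiating an SVF, that SVF is kept in
    ``svf`` so that taking logs is bookkeeping, never a numerical estimation.
    """

    displacement: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    svf: Optional[VelocityField] = None

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise InvalidInputError(
                f"Diffeo requires an (X, Y, Z, 3) displacement, got {self.displacement.shape}")
        if not np.all(np.isfinite(self.displacement)):
            raise InvalidInputError("Diffeo displacement must be finite")
        self.spacing = _as_triplet(self.spacing, "spacing")
        self.origin = _as_triplet(self.origin, "origin")

    @property
    def shape(self) -> tuple:
        return self.displacement.shape[:3]

    def max_displacement(self) -> float:
        return float(np.sqrt((self.displacement ** 2).sum(axis=-1)).max())


def check_same_grid(a, b, context: str = "") -> None:
    """Raise IncompatibleGridError unless a and b share shape and spacing."""
    if a.shape != b.shape:
        raise IncompatibleGridError(
            f"grid shape mismatch{': ' + context if context else ''}: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise IncompatibleGridError(
            f"grid spacing mismatch{': ' + context if context else ''}: {a.spacing} vs {b.spacing}")
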