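"""Core data model for calibrated density volumes, masks and rigid transforms.

All densities are held as floating point in mg HA/cm**3 regardless of how
they are stored on disk; every threshold in the analysis is expressed in
density units.  Grids are regular and isotropic.  Voxel indices are 0-based
and the physical position of voxel (i, j, k) is::

    (x, y, z) = origin + (k, j, i) * voxel_size

i.e. arrays are indexed (z, y, x) as is conventional for medical-image
arrays, while ``origin`` and all transform quantities live in physical
(x, y, z) millimetre coordinates with a voxel-centre convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GridMismatchError",
    "Grid",
    "ScanMeta",
    "DensityVolume",
    "BinaryMask",
    "RemodellingLabelVolume",
    "RigidTransform3D",
    "LABEL_OUTSIDE",
    "LABEL_UNCHANGED",
    "LABEL_FORMATION",
    "LABEL_RESORPTION",
]

# Remodelling label classes.
LABEL_OUTSIDE = 0      # outside the largest common volume
LABEL_UNCHANGED = 1
LABEL_FORMATION = 2
LABEL_RESORPTION = 3

#: minimum grid extent (voxels per axis) required by analysis operations
MIN_ANALYSIS_EXTENT = 8


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


class Grid(NamedTuple):
    """Geometry of a regular isotropic voxel grid."""

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float]

    def physical_points(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) array indices (i, j, k) to physical (x, y, z) mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx[:, ::-1] * self.voxel_size

    def isclose(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


def require_same_grid(*objs, what: str = "volumes") -> None:
    """Reject any shape/spacing/origin mismatch before analysis."""
    grids = [o.grid for o in objs]
    for g in grids[1:]:
        if not grids[0].isclose(g):
            raise GridMismatchError(
                f"{what} must share one grid; got {grids[0]} vs {g}"
            )


@dataclass(frozen=True)
class ScanMeta:
    """Free-form scan metadata: subject, timepoint and motion-artefact grade.

    ``quality_grade`` follows the 1 (no visible motion artefacts) to
    5 (severe motion artefacts) convention; ``None`` means ungraded.
    """

    subject: str = ""
    timepoint: str = ""
    quality_grade: int | None = None

    def __post_init__(self) -> None:
        if self.quality_grade is not None and self.quality_grade not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"quality_grade must be in 1..5 or None, got {self.quality_grade}"
            )


class _VolumeBase:
    """Shared grid bookkeeping for density, mask and label volumes."""

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float]

    def _check_grid(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def grid(self) -> Grid:
        return Grid(tuple(self.data.shape), float(self.voxel_size), tuple(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def check_analysis_size(self) -> None:
        if min(self.data.shape) < MIN_ANALYSIS_EXTENT:
            raise ValueError(
                f"analysis requires >= {MIN_ANALYSIS_EXTENT} voxels per axis, "
                f"got shape {self.data.shape}"
            )


@dataclass
class DensityVolume(_VolumeBase):
    """Calibrated 3D density field in mg HA/cm**3 on an isotropic grid.

    Negative densities are permitted (noise around soft tissue); NaN/inf
    are not.
    """

    data: np.ndarray
    voxel_size: float = 0.082
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.origin = tuple(float(v) for v in self.origin)
        self._check_grid()
        if not np.isfinite(self.data).all():
            raise ValueError("density values must be finite")

    def copy(self) -> "DensityVolume":
        return replace(self, data=self.data.copy())


@dataclass
class BinaryMask(_VolumeBase):
    """Boolean region on the grid of its paired volume (periosteal contour,
    trabecular compartment, LCV or bone segmentation)."""

    data: np.ndarray
    voxel_size: float = 0.082
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.origin = tuple(float(v) for v in self.origin)
        self._check_grid()

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self, what: str = "mask") -> None:
        if not self.data.any():
            raise ValueError(f"{what} has no true voxels")

    def centroid_physical(self) -> np.ndarray:
        """Physical (x, y, z) centroid of the true voxels, in mm."""
        self.require_nonempty()
        idx = np.argwhere(self.data).mean(axis=0)
        return self.grid.physical_points(idx)[0]

    def copy(self) -> "BinaryMask":
        return replace(self, data=self.data.copy())


@dataclass
class RemodellingLabelVolume(_VolumeBase):
    """Per-voxel remodelling class: 0 outside-LCV, 1 unchanged,
    2 formation, 3 resorption."""

    data: np.ndarray
    voxel_size: float = 0.082
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(np.uint8)
        self.origin = tuple(float(v) for v in self.origin)
        self._check_grid()
        if self.data.max(initial=0) > LABEL_RESORPTION:
            raise ValueError("labels must be in {0, 1, 2, 3}")

    def class_mask(self, label: int) -> np.ndarray:
        return self.data == label

    def counts(self) -> dict[int, int]:
        n = np.bincount(self.data.ravel(), minlength=4)
        return {k: int(n[k]) for k in range(4)}

    def copy(self) -> "RemodellingLabelVolume":
        return replace(self, data=self.data.copy())


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    return a


@dataclass(frozen=True)
class RigidTransform3D:
    """Rigid body map of physical points, y = R (x - c) + c + t.

    Used with the convention that it maps follow-up (moving) physical
    coordinates into the baseline (fixed) frame.  ``matrix`` is a proper
    rotation; Euler angles are reported in the intrinsic z-y-x convention,
    degrees.
    """

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", _as_vec3(self.translation))
        object.__setattr__(self, "center", _as_vec3(self.center))
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix must be orthonormal")
        if np.linalg.det(m) < 0:
            raise ValueError("rotation matrix must have determinant +1")

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3), np.zeros(3))

    @classmethod
    def from_euler(
        cls,
        angles_deg,
        translation=(0.0, 0.0, 0.0),
        center=(0.0, 0.0, 0.0),
    ) -> "RigidTransform3D":
        """Build from intrinsic z-y-x Euler angles in degrees,
        ``angles_deg = (rz, ry, rx)``."""
        m = Rotation.from_euler("ZYX", _as_vec3(angles_deg), degrees=True).as_matrix()
        return cls(m, translation, center)

    # -- queries ------------------------------------------------------
    @property
    def euler_zyx_deg(self) -> np.ndarray:
        """Intrinsic z-y-x Euler angles (rz, ry, rx), degrees."""
        return Rotation.from_matrix(self.matrix).as_euler("ZYX", degrees=True)

    @property
    def rotation_angle_deg(self) -> float:
        """Total rotation angle about the screw axis, degrees."""
        return float(np.degrees(Rotation.from_matrix(self.matrix).magnitude()))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (p - self.center) @ self.matrix.T + self.center + self.translation
        return out if np.asarray(points).ndim > 1 else out[0]

    def effective_translation(self) -> np.ndarray:
        """Translation b of the equivalent centre-free map y = R x + b."""
        return self.center + self.translation - self.matrix @ self.center

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            np.allclose(self.matrix, np.eye(3), atol=tol)
            and np.allclose(self.effective_translation(), 0.0, atol=tol)
        )

    # -- algebra (closed under composition and inversion) -------------
    def inverse(self) -> "RigidTransform3D":
        rt = self.matrix.T
        return RigidTransform3D(rt, -rt @ self.translation, self.center)

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """Return self o other (apply ``other`` first)."""
        m = self.matrix @ other.matrix
        # effective map: y = self(other(x)) = M x + b with b = self(other(0))
        b = self.apply(other.apply(np.zeros(3)))
        c = np.asarray(other.center)
        t = b + m @ c - c
        return RigidTransform3D(m, t, c)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "convention": "euler-zyx, physical-coords",
            "angles_deg": [float(a) for a in self.euler_zyx_deg],
            "translation_mm": [float(v) for v in self.translation],
            "center_mm": [float(v) for v in self.center],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform3D":
        return cls.from_euler(d["angles_deg"], d["translation_mm"], d["center_mm"])
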