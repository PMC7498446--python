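"""Core carriers: 3D intensity volumes and planes in world coordinates.

Conventions
-----------
* Arrays are indexed ``data[x, y, z]`` with world axes right / anterior /
  superior (RAS).
* The voxel-to-world map is diagonal: ``world = origin + index * spacing``.
  Rotated acquisitions are represented by resampling into this grid, never by
  an oblique affine, which keeps every downstream slice operation trivial.
* Angles follow the head-motion convention: yaw about the superior axis (z),
  pitch about the left-right axis (x), roll about the antero-posterior axis
  (y), composed as ``R = Rz(yaw) @ Rx(pitch) @ Ry(roll)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class Volume3D:
    """Scalar intensity grid with voxel spacing and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def world_center(self) -> np.ndarray:
        return self.index_to_world((np.asarray(self.shape) - 1) / 2.0)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume with the same grid geometry."""
        if data.shape != self.shape:
            raise ValueError("data shape mismatch with grid")
        return Volume3D(data, self.spacing, self.origin)

    def sample_world(self, points: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate intensities at world coordinates, shape (n, 3)."""
        idx = self.world_to_index(points).T
        return ndimage.map_coordinates(
            self.data.astype(float), idx, order=order, mode="constant", cval=cval
        )


@dataclass
class Plane:
    """Oriented plane ``normal . x == offset`` in world coordinates (mm)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be a nonzero finite vector")
        n = n / norm
        off = float(self.offset) / norm
        # canonical sign: first nonzero component positive
        for c in n:
            if abs(c) > 1e-12:
                if c < 0:
                    n = -n
                    off = -off
                break
        self.normal = n
        self.offset = float(off)

    @classmethod
    def from_point_normal(cls, point: np.ndarray, normal: np.ndarray) -> "Plane":
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        return cls(n, float(np.dot(n, np.asarray(point, dtype=float))))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def to_dict(self) -> dict:
        return {"normal": [float(c) for c in self.normal], "offset": self.offset}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(np.asarray(d["normal"], dtype=float), float(d["offset"]))


def rotation_matrix(yaw_deg: float, pitch_deg: float, roll_deg: float) -> np.ndarray:
    """Head rotation ``Rz(yaw) @ Rx(pitch) @ Ry(roll)`` (degrees)."""
    cy, sy = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    cp, sp = np.cos(np.radians(pitch_deg)), np.sin(np.radians(pitch_deg))
    cr, sr = np.cos(np.radians(roll_deg)), np.sin(np.radians(roll_deg))
    rz = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cp, -sp], [0.0, sp, cp]])
    ry = np.array([[cr, 0.0, sr], [0.0, 1.0, 0.0], [-sr, 0.0, cr]])
    return rz @ rx @ ry


def angular_error_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    """Unsigned angle between two plane normals, in degrees (sign-agnostic)."""
    a = np.asarray(n1, dtype=float)
    b = np.asarray(n2, dtype=float)
    c = abs(float(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotate_volume(
    vol: Volume3D,
    rot: np.ndarray,
    center_world: np.ndarray | None = None,
    order: int = 1,
    cval: float = 0.0,
) -> Volume3D:
    """Resample a volume rotated by ``rot`` about ``center_world``.

    The output voxel at world position p takes the input intensity at
    ``R^-1 (p - c) + c``: the *content* of the returned volume appears rotated
    by R relative to the input.  Geometry (grid, spacing, origin) is preserved.
    """
    c = vol.world_center() if center_world is None else np.asarray(center_world)
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    rinv = rot.T
    # input index = S^-1 (R^-1 (S * out_index + origin - c) + c - origin)
    mat = (rinv * spacing[None, :]) / spacing[:, None]
    off = (rinv @ (origin - c) + c - origin) / spacing
    data = ndimage.affine_transform(
        vol.data.astype(float), mat, offset=off, order=order, mode="constant", cval=cval
    )
    return Volume3D(data, vol.spacing, vol.origin)
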