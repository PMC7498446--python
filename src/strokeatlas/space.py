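"""Normalized (Talairach-like) reference space.

The normalized space is an axis-aligned bounding box with the anterior
commissure (AC) at the world origin and world axes pointing right / anterior /
superior (RAS, mm).  All atlas volumes live on a fixed grid inside this box;
the canonical brain is an ellipsoid whose extents reproduce the classical
Talairach proportions (width 132 mm, length 170 mm, height 114 mm).

The same geometric constants drive the procedural atlas and the head phantom
so that a phantom generated "in atlas pose" is exactly the atlas brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# --- canonical landmark coordinates (mm, RAS, AC at origin) ---------------
AC = np.array([0.0, 0.0, 0.0])
PC = np.array([0.0, -24.0, 0.0])
CORTEX_L = -66.0          # left cortical extreme (x)
CORTEX_R = 66.0           # right cortical extreme (x)
CORTEX_A = 68.0           # anterior cortical extreme (y)
CORTEX_P = -102.0         # posterior cortical extreme (y)
CORTEX_S = 72.0           # superior cortical extreme (z)
CORTEX_I = -42.0          # inferior cortical extreme (z)
CC_TOP = 28.0             # top of the corpus callosum (z)
OF_VENTRAL = -14.0        # most ventral orbito-frontal point (z)

# Brain ellipsoid implied by the cortical extremes.
BRAIN_CENTER = np.array([
    0.5 * (CORTEX_L + CORTEX_R),
    0.5 * (CORTEX_A + CORTEX_P),
    0.5 * (CORTEX_S + CORTEX_I),
])
BRAIN_SEMIAXES = np.array([
    0.5 * (CORTEX_R - CORTEX_L),
    0.5 * (CORTEX_A - CORTEX_P),
    0.5 * (CORTEX_S - CORTEX_I),
])

# Lateral ventricles: mirrored ellipsoids flanking the midline.
VENTRICLE_CENTERS = (
    np.array([-9.0, -18.0, 10.0]),
    np.array([9.0, -18.0, 10.0]),
)
VENTRICLE_SEMIAXES = np.array([5.0, 28.0, 11.0])

# Interhemispheric fissure: CSF slab about the midsagittal plane.
FISSURE_HALF_WIDTH = 1.0  # mm

# Fractions of the midsagittal cortex ellipse (semi-major a along y,
# semi-minor b along z, centered on BRAIN_CENTER) that place each landmark.
# These are the calibration constants for the statistical (ellipse-based)
# landmark localization; by construction they reproduce the stored landmarks
# exactly on the atlas-space ellipse.
_a = BRAIN_SEMIAXES[1]
_b = BRAIN_SEMIAXES[2]
ELLIPSE_LANDMARK_FRACTIONS = {
    "ac_major": (AC[1] - BRAIN_CENTER[1]) / _a,
    "ac_minor": (AC[2] - BRAIN_CENTER[2]) / _b,
    "pc_major": (PC[1] - BRAIN_CENTER[1]) / _a,
    "pc_minor": (PC[2] - BRAIN_CENTER[2]) / _b,
    "cc_top_minor": (CC_TOP - BRAIN_CENTER[2]) / _b,
    "of_ventral_minor": (OF_VENTRAL - BRAIN_CENTER[2]) / _b,
    "half_width_major": BRAIN_SEMIAXES[0] / _a,
}


@dataclass(frozen=True)
class NormalizedSpace:
    """Grid geometry of the normalized space plus its landmark coordinates.

    The grid is chosen so that no voxel center lies on the midsagittal plane
    x = 0; mirroring about the midplane is then an exact permutation of voxel
    indices (``i -> nx - 1 - i``).
    """

    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (-69.0, -105.0, -45.0)
    shape: tuple[int, int, int] = (70, 90, 60)
    landmarks: dict = field(default_factory=lambda: default_landmarks())

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.shape[k])
            for k in range(3)
        )

    def mirror_index(self, i: np.ndarray) -> np.ndarray:
        """Voxel x-index of the mirror image about the midsagittal plane."""
        return self.shape[0] - 1 - i


def default_landmarks() -> dict:
    return {
        "AC": AC.copy(),
        "PC": PC.copy(),
        "L": CORTEX_L,
        "R": CORTEX_R,
        "A": CORTEX_A,
        "P": CORTEX_P,
        "S": CORTEX_S,
        "I": CORTEX_I,
        "CC_top": CC_TOP,
        "OF_ventral": OF_VENTRAL,
    }


def brain_ellipsoid_mask(
    xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
    center: np.ndarray | None = None,
    semiaxes: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of the canonical brain ellipsoid on a world-coordinate grid."""
    c = BRAIN_CENTER if center is None else center
    s = BRAIN_SEMIAXES if semiaxes is None else semiaxes
    u = ((xs[:, None, None] - c[0]) / s[0]) ** 2
    v = ((ys[None, :, None] - c[1]) / s[1]) ** 2
    w = ((zs[None, None, :] - c[2]) / s[2]) ** 2
    return (u + v + w) <= 1.0


def ellipsoid_mask(
    xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
    center: np.ndarray, semiaxes: np.ndarray,
) -> np.ndarray:
    u = ((xs[:, None, None] - center[0]) / semiaxes[0]) ** 2
    v = ((ys[None, :, None] - center[1]) / semiaxes[1]) ** 2
    w = ((zs[None, None, :] - center[2]) / semiaxes[2]) ** 2
    return (u + v + w) <= 1.0
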