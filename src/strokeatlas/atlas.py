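"""Simplified co-registered atlases of anatomy and blood-supply territories.

Both label volumes live on the same normalized-space grid, share the cortex
and ventricle geometry with the head phantom, and are exactly left-right
mirror symmetric: every lateralized label has a mirror partner whose mask is
the voxelwise mirror image about the midsagittal plane.  Territory parcels
are planar/conical splits of the brain ellipsoid into the anterior (ACA),
middle (MCA, split into terminal and penetrating subterritories) and
posterior (PCA) cerebral artery territories; clinical fidelity of the
boundaries is a non-goal, but left-right exactness is mandatory because the
detection regime compares mirror pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as saio
from . import space as nspace
from .volume import Volume3D

# Deep (penetrating-branch / basal-ganglia) region geometry, per hemisphere.
DEEP_GRAY_CENTER = np.array([16.0, -16.0, 5.0])
DEEP_GRAY_SEMIAXES = np.array([12.0, 22.0, 14.0])
PENETRATING_SEMIAXES = np.array([15.0, 27.0, 17.0])

ANATOMY_NAMES = [
    "ventricle", "deep_gray",
    "white_ant_sup", "white_ant_inf", "white_post_sup", "white_post_inf",
    "brainstem_cerebellum", "occipital",
    "frontal_sup", "frontal_inf", "temporal_ant", "temporal_post",
    "parietal_ant", "parietal_post",
]
TERRITORY_NAMES = ["ACA", "MCA_terminal", "MCA_penetrating", "PCA"]


@dataclass
class LabelInfo:
    name: str
    laterality: str  # left | right | midline
    mirror_code: int


@dataclass
class AtlasBundle:
    """Co-registered anatomy + territory label volumes with legend and space."""

    anatomy: Volume3D
    territories: Volume3D
    ventricle_template: Volume3D
    legend: dict[int, LabelInfo]
    space: nspace.NormalizedSpace
    validate_grids: bool = True

    def __post_init__(self) -> None:
        if self.validate_grids:
            self.validate()

    def validate(self) -> None:
        if self.anatomy.shape != self.territories.shape:
            raise ValueError("anatomy and territories must share the grid shape")
        if self.anatomy.spacing != self.territories.spacing:
            raise ValueError("anatomy and territories must share voxel spacing")
        if self.ventricle_template.shape != self.anatomy.shape:
            raise ValueError("ventricle template must share the atlas grid")
        for code, info in self.legend.items():
            if info.laterality in ("left", "right"):
                if info.mirror_code not in self.legend:
                    raise ValueError(
                        f"lateralized label {code} ({info.name}) has no mirror_code"
                    )
                if self.legend[info.mirror_code].mirror_code != code:
                    raise ValueError(f"mirror codes of label {code} are not involutive")

    def mask(self, code: int) -> np.ndarray:
        vol = self.anatomy if code < 100 else self.territories
        return vol.data == code

    def brain_mask(self) -> np.ndarray:
        return self.territories.data > 0


def _lat_codes(base: int, index: int) -> tuple[int, int]:
    return base + 10 + 2 * index, base + 11 + 2 * index  # left, right


def make_space(resolution_mm: float = 2.0) -> nspace.NormalizedSpace:
    """Normalized-space grid at the given isotropic resolution.

    The grid is symmetric about x = 0 with no voxel center on the midplane,
    so mirroring is an exact index permutation.
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    r = float(resolution_mm)
    nx = 2 * int(np.ceil(70.0 / r))
    ny = int(np.ceil(182.0 / r))
    nz = int(np.ceil(124.0 / r))
    origin = (-(nx - 1) / 2.0 * r, -16.0 - (ny - 1) / 2.0 * r, 15.0 - (nz - 1) / 2.0 * r)
    return nspace.NormalizedSpace(spacing=(r, r, r), origin=origin, shape=(nx, ny, nz))


def build_simplified_atlas(
    resolution_mm: float = 2.0, seed_geometry: int = 0
) -> AtlasBundle:
    """Build the procedural atlas bundle at the requested grid resolution.

    Deterministic; ``seed_geometry`` is accepted for interface stability and
    recorded, but the canonical geometry is fixed.
    """
    space = make_space(resolution_mm)
    xs, ys, zs = space.world_coords()

    brain = nspace.brain_ellipsoid_mask(xs, ys, zs)
    white = nspace.ellipsoid_mask(
        xs, ys, zs, nspace.BRAIN_CENTER, nspace.BRAIN_SEMIAXES * 0.78
    )
    vent = np.zeros(brain.shape, dtype=bool)
    for c in nspace.VENTRICLE_CENTERS:
        vent |= nspace.ellipsoid_mask(xs, ys, zs, c, nspace.VENTRICLE_SEMIAXES)
    vent &= brain
    deep = np.zeros(brain.shape, dtype=bool)
    pen = np.zeros(brain.shape, dtype=bool)
    for sgn in (-1.0, 1.0):
        c = DEEP_GRAY_CENTER * np.array([sgn, 1.0, 1.0])
        deep |= nspace.ellipsoid_mask(xs, ys, zs, c, DEEP_GRAY_SEMIAXES)
        pen |= nspace.ellipsoid_mask(xs, ys, zs, c, PENETRATING_SEMIAXES)
    deep &= brain
    pen &= brain

    X = xs[:, None, None] + np.zeros_like(brain, dtype=float)
    Y = ys[None, :, None] + np.zeros_like(brain, dtype=float)
    Z = zs[None, None, :] + np.zeros_like(brain, dtype=float)
    left = X < 0

    # --- anatomy: sequential assignment tiles the brain exactly ------------
    anatomy = np.zeros(brain.shape, dtype=np.int16)
    remaining = brain.copy()

    def assign(mask: np.ndarray, idx: int) -> None:
        nonlocal remaining
        m = mask & remaining
        lcode, rcode = _lat_codes(0, idx)
        anatomy[m & left] = lcode
        anatomy[m & ~left] = rcode
        remaining &= ~m

    assign(vent, 0)                                  # ventricle
    assign(deep, 1)                                  # deep gray
    assign(white & (Y >= -17.0) & (Z >= 15.0), 2)    # white matter quadrants
    assign(white & (Y >= -17.0), 3)
    assign(white & (Z >= 15.0), 4)
    assign(white, 5)
    assign(Z < -25.0, 6)                             # brainstem-cerebellum block
    assign(Y < -60.0, 7)                             # occipital
    assign((Y > 24.0) & (Z >= 15.0), 8)              # frontal, sup/inf
    assign(Y > 24.0, 9)
    assign((Z < 5.0) & (Y >= -20.0), 10)             # temporal, ant/post
    assign(Z < 5.0, 11)
    assign(Y >= -20.0, 12)                           # parietal, ant/post
    assign(np.ones_like(brain), 13)

    # --- territories: every brain voxel gets exactly one -------------------
    territories = np.zeros(brain.shape, dtype=np.int16)
    remaining = brain.copy()

    def assign_t(mask: np.ndarray, idx: int) -> None:
        nonlocal remaining
        m = mask & remaining
        lcode, rcode = _lat_codes(100, idx)
        territories[m & left] = lcode
        territories[m & ~left] = rcode
        remaining &= ~m

    assign_t((Y < -60.0) | (Z < -25.0), 3)    # PCA (posterior / inferior)
    assign_t(pen, 2)                          # MCA penetrating (deep)
    assign_t(np.abs(X) <= 14.0, 0)            # ACA (medial strip)
    assign_t(np.ones_like(brain), 1)          # MCA terminal (remainder)

    legend: dict[int, LabelInfo] = {}
    for idx, name in enumerate(ANATOMY_NAMES):
        lcode, rcode = _lat_codes(0, idx)
        legend[lcode] = LabelInfo(f"{name}_left", "left", rcode)
        legend[rcode] = LabelInfo(f"{name}_right", "right", lcode)
    for idx, name in enumerate(TERRITORY_NAMES):
        lcode, rcode = _lat_codes(100, idx)
        legend[lcode] = LabelInfo(f"{name}_left", "left", rcode)
        legend[rcode] = LabelInfo(f"{name}_right", "right", lcode)

    vt_l, vt_r = _lat_codes(0, 0)
    ventricle_template = ((anatomy == vt_l) | (anatomy == vt_r)).astype(np.uint8)
    return AtlasBundle(
        anatomy=Volume3D(anatomy, space.spacing, space.origin),
        territories=Volume3D(territories, space.spacing, space.origin),
        ventricle_template=Volume3D(ventricle_template, space.spacing, space.origin),
        legend=legend,
        space=space,
    )


def mirror_labels(labels: np.ndarray, legend: dict[int, LabelInfo]) -> np.ndarray:
    """Mirror a label volume about the midsagittal plane, swapping codes."""
    flipped = labels[::-1, :, :].copy()
    out = flipped.copy()
    for code, info in legend.items():
        if info.laterality in ("left", "right"):
            out[flipped == code] = info.mirror_code
    return out


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def write_atlas(bundle: AtlasBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    saio.write_volume(bundle.anatomy, directory / "anatomy.nii.gz")
    saio.write_volume(bundle.territories, directory / "territories.nii.gz")
    saio.write_volume(bundle.ventricle_template, directory / "ventricles.nii.gz")
    legend = {
        str(code): {
            "name": info.name,
            "laterality": info.laterality,
            "mirror_code": info.mirror_code,
        }
        for code, info in bundle.legend.items()
    }
    meta = {
        "legend": legend,
        "space": {
            "spacing": list(bundle.space.spacing),
            "origin": list(bundle.space.origin),
            "shape": list(bundle.space.shape),
            "landmarks": {
                k: (list(v) if isinstance(v, np.ndarray) else v)
                for k, v in bundle.space.landmarks.items()
            },
        },
    }
    (directory / "legend.json").write_text(json.dumps(meta, indent=1))


def read_atlas(directory: str | Path) -> AtlasBundle:
    directory = Path(directory)
    anatomy = saio.read_volume(directory / "anatomy.nii.gz")
    territories = saio.read_volume(directory / "territories.nii.gz")
    ventricles = saio.read_volume(directory / "ventricles.nii.gz")
    anatomy = anatomy.like(anatomy.data.astype(np.int16))
    territories = territories.like(territories.data.astype(np.int16))
    ventricles = ventricles.like(ventricles.data.astype(np.uint8))
    meta = json.loads((directory / "legend.json").read_text())
    legend = {
        int(code): LabelInfo(d["name"], d["laterality"], int(d["mirror_code"]))
        for code, d in meta["legend"].items()
    }
    sp = meta["space"]
    landmarks = {
        k: (np.asarray(v, dtype=float) if isinstance(v, list) else float(v))
        for k, v in sp["landmarks"].items()
    }
    space = nspace.NormalizedSpace(
        spacing=tuple(sp["spacing"]), origin=tuple(sp["origin"]),
        shape=tuple(sp["shape"]), landmarks=landmarks,
    )
    if anatomy.spacing != territories.spacing:
        raise ValueError("anatomy and territories volumes have unequal spacing")
    return AtlasBundle(
        anatomy=anatomy, territories=territories, ventricle_template=ventricles,
        legend=legend, space=space,
    )
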