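"""Lesion segmentation: WMHs, DWI infarcts, CT brain extraction, contours.

Contours are traced along voxel-edge "cracks" (vertices at half-integer
pixel coordinates, converted to mm), which makes the mask -> contour -> mask
round trip voxel-exact for any shape; rasterization uses even-odd filling
(XOR accumulation), so nested contours cut holes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

from .volume import Plane, Volume3D

CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ContourSet:
    """Per-slice closed polygons (mm, slice coordinates) on a reference grid."""

    slices: dict[int, list[np.ndarray]]
    grid_shape: tuple[int, int, int]
    grid_spacing: tuple[float, float, float]
    grid_origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        for k, polys in self.slices.items():
            if not (0 <= k < self.grid_shape[2]):
                raise ValueError(f"slice index {k} outside the grid")
            for p in polys:
                p = np.asarray(p)
                if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 4:
                    raise ValueError("polygons need >= 3 vertices plus closure")
                if not np.allclose(p[0], p[-1]):
                    raise ValueError("open polygon: first and last vertex must coincide")

    @property
    def n_polygons(self) -> int:
        return sum(len(p) for p in self.slices.values())

    def is_empty(self) -> bool:
        return self.n_polygons == 0

    @classmethod
    def empty_like(cls, vol: Volume3D) -> "ContourSet":
        return cls({}, vol.shape, vol.spacing, vol.origin)


def _polygon_area(p: np.ndarray) -> float:
    x, y = p[:-1, 0], p[:-1, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _trace_slice(mask2d: np.ndarray) -> list[np.ndarray]:
    """Trace crack-edge boundary loops of a binary 2D mask.

    Directed edges keep the interior on the left, so outer boundaries come
    out counter-clockwise and holes clockwise.  At corner junctions where two
    loops touch diagonally, the left turn is preferred, which keeps the loops
    separate.
    """
    if not mask2d.any():
        return []
    nx, ny = mask2d.shape
    padded = np.zeros((nx + 2, ny + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask2d
    # Directed edges as (start, end) vertex pairs; vertices are pixel-corner
    # coordinates doubled to keep them integer: corner (i-0.5, j-0.5) -> (2i-1, 2j-1).
    edges: dict[tuple, list[tuple]] = {}
    px, py = np.nonzero(padded)
    for i, j in zip(px, py):
        corners = (
            (2 * i - 1, 2 * j - 1), (2 * i + 1, 2 * j - 1),
            (2 * i + 1, 2 * j + 1), (2 * i - 1, 2 * j + 1),
        )
        if not padded[i, j - 1]:  # bottom edge, walk +x
            edges.setdefault(corners[0], []).append(corners[1])
        if not padded[i + 1, j]:  # right edge, walk +y
            edges.setdefault(corners[1], []).append(corners[2])
        if not padded[i, j + 1]:  # top edge, walk -x
            edges.setdefault(corners[2], []).append(corners[3])
        if not padded[i - 1, j]:  # left edge, walk -y
            edges.setdefault(corners[3], []).append(corners[0])

    loops = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        prev_dir = None
        v = start
        while True:
            nxts = edges[v]
            if len(nxts) == 1 or prev_dir is None:
                nxt = nxts[0]
            else:
                # prefer the left turn relative to the incoming direction
                def turn(c):
                    d = (c[0] - v[0], c[1] - v[1])
                    return prev_dir[0] * d[1] - prev_dir[1] * d[0]
                nxt = max(nxts, key=turn)
            nxts.remove(nxt)
            if not nxts:
                del edges[v]
            prev_dir = (nxt[0] - v[0], nxt[1] - v[1])
            v = nxt
            if v == start:
                loop.append(v)
                break
            loop.append(v)
        loops.append(np.asarray(loop, dtype=float))

    out = []
    for loop in loops:
        # doubled padded corners -> index coords: (c - 2) / 2 relative to mask2d
        pts = (loop - 2.0) / 2.0
        # drop collinear intermediate vertices
        keep = [0]
        for m in range(1, len(pts) - 1):
            d1 = pts[m] - pts[keep[-1]]
            d2 = pts[m + 1] - pts[m]
            if d1[0] * d2[1] - d1[1] * d2[0] != 0:
                keep.append(m)
        keep.append(len(pts) - 1)
        out.append(pts[keep])
    return out


def contours_from_mask(mask: Volume3D) -> ContourSet:
    """Per-slice crack-edge contours of a binary mask volume."""
    data = mask.data > 0
    slices: dict[int, list[np.ndarray]] = {}
    sx, sy = mask.spacing[0], mask.spacing[1]
    ox, oy = mask.origin[0], mask.origin[1]
    for k in range(mask.shape[2]):
        loops = _trace_slice(data[:, :, k])
        if not loops:
            continue
        polys = []
        for p in loops:
            mm = np.column_stack([ox + p[:, 0] * sx, oy + p[:, 1] * sy])
            polys.append(mm)
        slices[k] = polys
    return ContourSet(slices, mask.shape, mask.spacing, mask.origin)


def mask_from_contours(cs: ContourSet, grid: Volume3D) -> Volume3D:
    """Rasterize a contour set onto a grid with the even-odd rule."""
    out = np.zeros(grid.shape, dtype=np.uint8)
    sx, sy = grid.spacing[0], grid.spacing[1]
    ox, oy = grid.origin[0], grid.origin[1]
    for k, polys in cs.slices.items():
        if not (0 <= k < grid.shape[2]):
            raise ValueError(f"slice index {k} outside the target grid")
        acc = np.zeros(grid.shape[:2], dtype=bool)
        for p in polys:
            p = np.asarray(p, dtype=float)
            if not np.allclose(p[0], p[-1]):
                raise ValueError("open polygon")
            rr = (p[:, 0] - ox) / sx
            cc = (p[:, 1] - oy) / sy
            fr, fc = draw_polygon(rr, cc, shape=grid.shape[:2])
            fill = np.zeros(grid.shape[:2], dtype=bool)
            fill[fr, fc] = True
            acc ^= fill
        out[:, :, k] = acc
    return Volume3D(out, grid.spacing, grid.origin)


# --------------------------------------------------------------------------
# WMH segmentation and quantification
# --------------------------------------------------------------------------

@dataclass
class WmhLocus:
    volume_ml: float
    centroid_mm: tuple[float, float, float]
    distance_to_ventricles_mm: float | None
    periventricular: bool


@dataclass
class WmhReport:
    n_loci: int
    total_volume_ml: float
    loci: list[WmhLocus]

    def to_dict(self) -> dict:
        return {
            "n_loci": self.n_loci,
            "total_volume_ml": self.total_volume_ml,
            "loci": [vars(l) for l in self.loci],
        }


def segment_wmh(
    t1: Volume3D,
    t2: Volume3D,
    pd: Volume3D,
    ranges: dict[str, tuple[float, float]],
    brain_mask: Volume3D | None = None,
) -> tuple[Volume3D, ContourSet]:
    """Multi-modal WMH segmentation by intensity-range intersection.

    A voxel is WMH iff its intensity falls inside the configured
    (lo, hi) range in *all three* co-registered pulse sequences (and inside
    the brain mask, if one is supplied).
    """
    vols = {"t1": t1, "t2": t2, "pd": pd}
    for name, v in vols.items():
        if v.shape != t1.shape or v.spacing != t1.spacing:
            raise ValueError(f"{name} volume grid mismatch")
        if name not in ranges:
            raise ValueError(f"missing intensity range for {name}")
    mask = np.ones(t1.shape, dtype=bool)
    for name, v in vols.items():
        lo, hi = ranges[name]
        mask &= (v.data >= lo) & (v.data <= hi)
    if brain_mask is not None:
        if brain_mask.shape != t1.shape:
            raise ValueError("brain mask grid mismatch")
        mask &= brain_mask.data > 0
    mvol = t1.like(mask.astype(np.uint8))
    return mvol, contours_from_mask(mvol)


def quantify_wmh(
    mask: Volume3D, ventricle_mask: Volume3D, periventricular_mm: float = 10.0
) -> WmhReport:
    """Count WMH loci and relate each to the ventricular surface."""
    if mask.shape != ventricle_mask.shape:
        raise ValueError("mask grids must match")
    lab, n = ndimage.label(mask.data > 0, structure=CONN26)
    have_vent = bool(np.any(ventricle_mask.data > 0))
    if not have_vent:
        warnings.warn("empty ventricle mask: distances reported as absent")
        dist = None
    else:
        dist = ndimage.distance_transform_edt(
            ventricle_mask.data == 0, sampling=mask.spacing
        )
    loci = []
    vox_ml = mask.voxel_volume_ml()
    for c in range(1, n + 1):
        comp = lab == c
        nvox = int(comp.sum())
        centroid = mask.index_to_world(np.argwhere(comp).mean(axis=0))
        if dist is None:
            d = None
            peri = False
        else:
            d = float(dist[comp].min())
            peri = d <= periventricular_mm
        loci.append(WmhLocus(nvox * vox_ml, tuple(centroid), d, peri))
    return WmhReport(n, float(sum(l.volume_ml for l in loci)), loci)


# --------------------------------------------------------------------------
# CT brain extraction and CSF removal
# --------------------------------------------------------------------------

def extract_brain_ct(volume: Volume3D, skull_threshold: float = 200.0) -> Volume3D:
    """Brain (intracranial) mask from CT by skull-based thresholding.

    Thresholds the bright skull shell, fills its interior, and keeps the
    largest interior component, eroded in-plane by one voxel to trim the
    subarachnoid rim.
    """
    data = volume.data
    skull = data >= skull_threshold
    if skull.sum() < 100:
        raise ValueError("no skull shell found (is this a CT-style volume?)")
    filled = ndimage.binary_fill_holes(skull)
    interior = filled & ~skull
    if not interior.any():
        raise ValueError("skull shell encloses no interior")
    lab, n = ndimage.label(interior, structure=CONN26)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    brain = lab == (1 + int(np.argmax(sizes)))
    brain = ndimage.binary_erosion(brain, structure=np.ones((3, 3, 1), dtype=bool))
    return volume.like(brain.astype(np.uint8))


def remove_csf(
    volume: Volume3D,
    brain_mask: Volume3D,
    ventricle_template: Volume3D,
    dilate_mm: float = 4.0,
    min_separation: float = 20.0,
) -> Volume3D:
    """Remove CSF from the brain mask, confined to the ventricle-template ROI.

    The template (individualized onto the scan grid) limits leakage into
    hypodense infarcts whose density overlaps CSF.  The CSF/tissue threshold
    is found from the ROI intensity histogram; if the ROI shows no bimodal
    CSF/tissue separation (mode distance below ``min_separation`` intensity
    units), nothing is removed.
    """
    tmpl = ventricle_template.data > 0
    if not tmpl.any():
        raise ValueError("empty ventricle template")
    if dilate_mm > 0:
        it = max(1, int(round(dilate_mm / min(volume.spacing))))
        roi = ndimage.binary_dilation(tmpl, structure=CONN26, iterations=it)
    else:
        roi = tmpl
    roi = roi & (brain_mask.data > 0)
    vals = volume.data[roi]
    if vals.size == 0:
        return brain_mask
    thr = float(threshold_otsu(vals)) if np.ptp(vals) > 1e-6 else -np.inf
    low = vals[vals < thr]
    high = vals[vals >= thr]
    if low.size == 0 or high.size == 0 or (high.mean() - low.mean()) < min_separation:
        return brain_mask
    csf = roi & (volume.data < thr)
    return brain_mask.like(((brain_mask.data > 0) & ~csf).astype(np.uint8))


# --------------------------------------------------------------------------
# DWI infarct segmentation by left/right PDF divergence
# --------------------------------------------------------------------------

def segment_infarct_dwi(
    volume: Volume3D,
    msp: Plane,
    ratio_threshold: float = 3.0,
    n_bins: int = 64,
    min_component_ml: float = 1.0,
    brain_mask: Volume3D | None = None,
    eps: float = 1e-6,
) -> tuple[Volume3D, float]:
    """Segment a unilateral infarct from hemispheric PDF divergence.

    Intensity bins where one hemisphere's probability density exceeds the
    mirror hemisphere's by ``ratio_threshold`` are flagged; voxels of the
    over-represented side falling in flagged bins are marked, then cleaned
    by morphological opening and a minimum component volume.
    """
    if brain_mask is not None:
        inside = brain_mask.data > 0
    else:
        thr = float(threshold_otsu(volume.data)) if np.ptp(volume.data) > 1e-6 else np.inf
        inside = volume.data > thr
    if not inside.any():
        raise ValueError("no brain voxels for hemispheric comparison")
    nx, ny, nz = volume.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    world = volume.index_to_world(
        np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    )
    sd = msp.signed_distance(world).reshape(volume.shape)
    left = inside & (sd < 0)
    right = inside & (sd > 0)
    n_l, n_r = left.sum(), right.sum()
    if n_l == 0 or n_r == 0 or abs(np.log(n_l / n_r)) > 0.2:
        warnings.warn("hemispheres have grossly unequal voxel counts; MSP suspect")

    vals = volume.data[inside]
    lo, hi = np.percentile(vals, [0.5, 99.5])
    if hi - lo < 1e-6:
        return volume.like(np.zeros(volume.shape, dtype=np.uint8)), 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    h_l, _ = np.histogram(volume.data[left], bins=edges)
    h_r, _ = np.histogram(volume.data[right], bins=edges)
    p_l = (h_l + eps) / (h_l + eps).sum()
    p_r = (h_r + eps) / (h_r + eps).sum()

    mask = np.zeros(volume.shape, dtype=bool)
    binned = np.clip(np.digitize(volume.data, edges) - 1, 0, n_bins - 1)
    flag_l = p_l / p_r >= ratio_threshold
    flag_r = p_r / p_l >= ratio_threshold
    mask |= left & flag_l[binned]
    mask |= right & flag_r[binned]

    mask = ndimage.binary_opening(mask, structure=ndimage.generate_binary_structure(3, 1))
    lab, n = ndimage.label(mask, structure=CONN26)
    vox_ml = volume.voxel_volume_ml()
    keep = np.zeros_like(mask)
    for c in range(1, n + 1):
        comp = lab == c
        if comp.sum() * vox_ml >= min_component_ml:
            keep |= comp
    vol_ml = float(keep.sum() * vox_ml)
    return volume.like(keep.astype(np.uint8)), vol_ml
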