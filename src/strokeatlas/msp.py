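"""Midsagittal plane (MSP) extraction by the Kullback-Leibler measure.

The MSP carries the interhemispheric fissure, whose CSF content gives the
midsagittal slice an intensity distribution maximally different from
parenchymal slices.  The extractor scores candidate planes by a symmetrized
KL divergence between the candidate's intensity histogram and that of a
lateral reference slice, in two stages:

* coarse - scan grid-aligned sagittal slices inside a volume of interest
  (VOI) around the central slice, using the first VOI slice as the
  reference; pick the slice with maximal KL measure;
* fine - parameterize an oblique plane by the sagittal offsets of three
  corner points of the coarse slice and hill-climb the same KL objective
  over a shrinking search range.

A tilt-extended variant first estimates the head orientation from
ellipse fits to the skull cross-section on axial slices, counter-rotates the
volume, and composes the pre-rotation back into the returned plane.  It is
the path for emergency-room CT with large head tilt and thick slices, where
the base search range is insufficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel, find_contours

from .volume import Plane, Volume3D, rotate_volume


@dataclass
class IntensityHistogram:
    """Discrete intensity distribution on shared bin edges."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 3:
            raise ValueError("need at least 2 bins")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")
        s = self.probabilities.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {s})")

    @classmethod
    def from_values(cls, values: np.ndarray, bin_edges: np.ndarray) -> "IntensityHistogram":
        counts, _ = np.histogram(values, bins=bin_edges)
        total = counts.sum()
        if total == 0:
            probs = np.full(len(bin_edges) - 1, 1.0 / (len(bin_edges) - 1))
        else:
            probs = counts / total
        return cls(bin_edges, probs)


def kl_measure(p: IntensityHistogram, q: IntensityHistogram, eps: float = 1e-6) -> float:
    """Symmetrized KL divergence (J-divergence) between two histograms.

    Both distributions are smoothed by adding ``eps`` per bin and
    renormalized, so the measure is finite for any inputs, symmetric in its
    arguments, and zero iff the histograms are identical.
    """
    if p.bin_edges.shape != q.bin_edges.shape or not np.allclose(p.bin_edges, q.bin_edges):
        raise ValueError("histograms must share identical binning")
    return _kl_from_probs(p.probabilities, q.probabilities, eps)


def _kl_from_probs(pp: np.ndarray, qq: np.ndarray, eps: float = 1e-6) -> float:
    a = pp + eps
    a = a / a.sum()
    b = qq + eps
    b = b / b.sum()
    return float(np.sum(a * np.log(a / b)) + np.sum(b * np.log(b / a)))


@dataclass
class MspParams:
    n_bins: int = 64
    voi_half_fraction: float = 0.2     # VOI half-width as a fraction of nx
    air_threshold: float | None = None  # None -> Otsu air/tissue split
    fine_scales: tuple[float, ...] = (4.0, 2.0, 1.0, 0.5, 0.25)  # in slice spacings
    fine_max_moves: int = 60           # per scale, per sweep budget
    init_grid_steps: int = 12           # coarse tilt grid half-width, in fine_scales[0] units
    max_plane_samples: int = 96        # per in-plane axis
    skull_threshold: float = 200.0     # tilt path: skull shell intensity floor


def _tissue_band(vol: Volume3D, params: MspParams, air_thr: float) -> tuple[float, float]:
    """Intensity band of soft tissue: above air, below any bright bone shell.

    A skull-tangent oblique plane is as "different" from a parenchymal
    reference as the fissure plane is, so on CT the bone intensities must be
    excluded from the histograms; bone is only assumed present when a
    substantial fraction of non-air voxels exceeds ``skull_threshold``.
    """
    vals = vol.data[vol.data > air_thr]
    if vals.size < 100:
        raise ValueError("no symmetry signal: volume is (nearly) empty above air threshold")
    bone_frac = float(np.mean(vals >= params.skull_threshold))
    bone_thr = params.skull_threshold if bone_frac >= 0.02 else np.inf
    return air_thr, bone_thr


def _bin_edges(vol: Volume3D, params: MspParams, air_thr: float, bone_thr: float) -> np.ndarray:
    vals = vol.data[(vol.data > air_thr) & (vol.data < bone_thr)]
    if vals.size < 100:
        raise ValueError("no symmetry signal: volume is (nearly) empty above air threshold")
    lo, hi = np.percentile(vals, [1, 99])
    if hi - lo < 1e-6:
        raise ValueError("no symmetry signal: constant-intensity volume")
    # margin keeps low-percentile CSF inside the histogram support
    margin = 0.08 * (hi - lo)
    return np.linspace(lo - margin, hi + margin, params.n_bins + 1)


def _air_threshold(vol: Volume3D, params: MspParams) -> float:
    """Threshold just above the background (air) intensity mode.

    Air dominates the volume outside the skull; its histogram mode plus a
    small fraction of the dynamic range excludes background while keeping
    CSF, whose presence on the interhemispheric fissure *is* the signal the
    KL measure keys on.
    """
    if params.air_threshold is not None:
        return params.air_threshold
    lo, hi = float(vol.data.min()), float(vol.data.max())
    if hi - lo < 1e-6:
        raise ValueError("no symmetry signal: constant-intensity volume")
    counts, edges = np.histogram(vol.data, bins=128)
    mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
    return mode + 0.05 * (hi - lo)


def _slice_probs(data: np.ndarray, i: int, edges: np.ndarray, air_thr: float,
                 bone_thr: float = np.inf) -> np.ndarray:
    vals = data[i]
    vals = vals[(vals > air_thr) & (vals < bone_thr)]
    counts, _ = np.histogram(vals, bins=edges)
    total = counts.sum()
    nb = len(edges) - 1
    return counts / total if total else np.full(nb, 1.0 / nb)


def extract_msp(volume: Volume3D, params: MspParams | None = None) -> Plane:
    """Extract the midsagittal plane with the coarse/fine KL search."""
    params = params or MspParams()
    nx, ny, nz = volume.shape
    if nx < 16:
        raise ValueError("need at least 16 sagittal slices")
    air_thr = _air_threshold(volume, params)
    air_thr, bone_thr = _tissue_band(volume, params, air_thr)
    edges = _bin_edges(volume, params, air_thr, bone_thr)
    data = volume.data

    center = nx // 2
    half = max(4, int(round(params.voi_half_fraction * nx)))
    lo = max(0, center - half)
    hi = min(nx - 1, center + half)
    ref_probs = _slice_probs(data, lo, edges, air_thr, bone_thr)

    scores = np.array([
        _kl_from_probs(_slice_probs(data, i, edges, air_thr, bone_thr), ref_probs)
        for i in range(lo, hi + 1)
    ])
    # near-ties are broken toward the volume center: when the fissure is
    # tilted no grid slice is special and the score profile is flat, so the
    # centermost high scorer is the best fine-stage pivot
    best = np.flatnonzero(scores >= 0.9 * scores.max())
    coarse = int(lo + best[np.argmin(np.abs(lo + best - center))])

    # --- fine stage: perturb three corner points of the coarse slice -------
    stride = max(1, int(np.ceil(max(ny, nz) / params.max_plane_samples)))
    yy, zz = np.meshgrid(
        np.arange(0, ny, stride, dtype=float),
        np.arange(0, nz, stride, dtype=float),
        indexing="ij",
    )
    fy = yy / max(ny - 1, 1)
    fz = zz / max(nz - 1, 1)

    def objective(offsets: np.ndarray) -> float:
        o1, o2, o3 = offsets
        x = coarse + o1 + (o2 - o1) * fy + (o3 - o1) * fz
        valid = (x >= 0) & (x <= nx - 1)
        if valid.mean() < 0.5:
            return -np.inf
        coords = np.stack([x[valid], yy[valid], zz[valid]])
        vals = ndimage.map_coordinates(data, coords, order=1, mode="nearest")
        vals = vals[(vals > air_thr) & (vals < bone_thr)]
        counts, _ = np.histogram(vals, bins=edges)
        total = counts.sum()
        if total == 0:
            return -np.inf
        return _kl_from_probs(counts / total, ref_probs)

    # Search directions in corner-offset space: rigid translation along x,
    # pivots about the plane center (pure tilts), and single-corner moves.
    directions = [
        np.array([1.0, 1.0, 1.0]),      # translation
        np.array([-0.5, 0.5, -0.5]),    # pivot about center, tilt in y
        np.array([-0.5, -0.5, 0.5]),    # pivot about center, tilt in z
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        np.array([0.0, 0.0, 1.0]),
    ]
    # coarse tilt grid over the two pivots bridges local dips in the KL
    # landscape before the hill climb refines
    d_py, d_pz = directions[1], directions[2]
    step0 = params.fine_scales[0]
    offsets = np.zeros(3)
    score = objective(offsets)
    g = params.init_grid_steps
    d_tr = directions[0]
    for a in range(-g, g + 1):
        for b in range(-g, g + 1):
            for t in (-1, 0, 1):
                if a == 0 and b == 0 and t == 0:
                    continue
                trial = (a * d_py + b * d_pz + t * d_tr) * step0
                s = objective(trial)
                if s > score:
                    offsets, score = trial, s
    for scale in params.fine_scales:
        moves = 0
        improved = True
        while improved and moves < params.fine_max_moves:
            improved = False
            for d in directions:
                for sgn in (1.0, -1.0):
                    trial = offsets + sgn * scale * d
                    s = objective(trial)
                    if s > score + 1e-12:
                        offsets, score = trial, s
                        improved = True
                        moves += 1
                        break

    o1, o2, o3 = offsets
    p1 = volume.index_to_world([coarse + o1, 0.0, 0.0])
    p2 = volume.index_to_world([coarse + o2, float(ny - 1), 0.0])
    p3 = volume.index_to_world([coarse + o3, 0.0, float(nz - 1)])
    normal = np.cross(p2 - p1, p3 - p1)
    return Plane.from_point_normal(p1, normal)


# --------------------------------------------------------------------------
# Tilt-extended extraction (skull-fit pre-rotation)
# --------------------------------------------------------------------------

def _skull_slice_ellipse(slc: np.ndarray, thr: float) -> EllipseModel | None:
    mask = slc > thr
    if mask.sum() < 60:
        return None
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    pts = max(contours, key=len)
    if len(pts) < 20:
        return None
    model = EllipseModel.from_estimate(pts)
    return model if model else None


def estimate_head_orientation(
    volume: Volume3D, skull_threshold: float = 200.0
) -> tuple[float, float, float]:
    """Estimate (yaw, pitch, roll) in degrees from skull ellipse fits.

    Yaw comes from the in-plane orientation of the skull's major axis on
    axial slices; pitch and roll from the slicewise drift of the skull
    center along the superior axis.
    """
    nx, ny, nz = volume.shape
    zs, yaws, cxs, cys = [], [], [], []
    for k in range(nz):
        model = _skull_slice_ellipse(volume.data[:, :, k], skull_threshold)
        if model is None:
            continue
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
        if a < b:
            a, b = b, a
            theta += np.pi / 2.0
        # major axis direction in (x, y) index coords; unrotated head has the
        # major axis along +y, so yaw = angle from +y
        yaw = np.degrees(theta) - 90.0
        yaw = (yaw + 90.0) % 180.0 - 90.0
        zs.append(volume.axis_coords(2)[k])
        yaws.append(yaw)
        cxs.append(volume.origin[0] + xc * volume.spacing[0])
        cys.append(volume.origin[1] + yc * volume.spacing[1])
    if len(zs) < 5:
        raise ValueError("no skull detected on axial slices; use the MR path (extract_msp)")
    zs = np.asarray(zs)
    # restrict to the mid band where the cross-section is a stable ellipse
    order = np.argsort(zs)
    sel = order[len(order) // 4: max(len(order) // 4 + 1, 3 * len(order) // 4)]
    yaw = float(np.median(np.asarray(yaws)[sel]))
    z = zs[sel]
    cx = np.asarray(cxs)[sel]
    cy = np.asarray(cys)[sel]
    if np.ptp(z) < 1e-6:
        return yaw, 0.0, 0.0
    sx = np.polyfit(z, cx, 1)[0]
    sy = np.polyfit(z, cy, 1)[0]
    # center drift dcx/dz = tan(roll), dcy/dz = -tan(pitch) for small angles
    roll = float(np.degrees(np.arctan(sx)))
    pitch = float(-np.degrees(np.arctan(sy)))
    return yaw, pitch, roll


def extract_msp_tilted(volume: Volume3D, params: MspParams | None = None) -> Plane:
    """MSP for large head tilt: skull-fit pre-rotation then the KL search."""
    from .volume import rotation_matrix

    params = params or MspParams()
    yaw, pitch, roll = estimate_head_orientation(volume, params.skull_threshold)
    rot = rotation_matrix(yaw, pitch, roll)
    center = volume.world_center()
    if max(abs(yaw), abs(pitch), abs(roll)) > 0.5:
        aligned = rotate_volume(volume, rot.T, center_world=center, order=1)
    else:
        aligned = volume
        rot = np.eye(3)
    plane_aligned = extract_msp(aligned, params)
    # point p' in the aligned volume corresponds to c + R (p' - c) originally
    normal = rot @ plane_aligned.normal
    point_aligned = plane_aligned.normal * plane_aligned.offset
    point = center + rot @ (point_aligned - center)
    return Plane.from_point_normal(point, normal)
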