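"""Ellipse-based landmark estimation and the piecewise-linear atlas transform.

The normalization follows the Talairach scheme: point landmarks (AC, PC) and
cortical extremes partition the brain into axis-aligned cuboids which are
scaled piecewise linearly onto the corresponding atlas cuboids.  The default
partition is 2 lateral x 3 antero-posterior x 2 vertical = 12 regions
(7 scales + 3 translations + 3 orientations = 13 degrees of freedom); the
extended form splits the vertical axis additionally at the top of the corpus
callosum and the most ventral orbito-frontal point, giving 24 regions and 15
degrees of freedom.

Landmarks are localized *statistically*: the cortex outline on a maximum
intensity projection (MIP) slab around the midsagittal plane is fitted with
an ellipse, and each landmark is placed at a fixed fraction of the ellipse
axes.  The fractions are calibrated so that, on the normalized-space atlas
ellipse, the produced landmarks coincide exactly with the stored ones.  This
path needs no visible commissures and therefore works on thick-slice CT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel, find_contours, label as cc_label

from . import space as nspace
from .msp import MspParams, extract_msp, extract_msp_tilted
from .volume import Plane, Volume3D


@dataclass
class LandmarkSet:
    """Talairach landmarks in an aligned (RAS, mm) coordinate frame.

    ``AC`` and ``PC`` are 3-points; the six cortical landmarks are single
    coordinates along their axes.  The optional extended landmarks are the
    superior corpus-callosum and the most ventral orbito-frontal coordinate.
    """

    AC: np.ndarray
    PC: np.ndarray
    L: float
    R: float
    A: float
    P: float
    S: float
    I: float
    CC_top: float | None = None
    OF_ventral: float | None = None

    def __post_init__(self) -> None:
        self.AC = np.asarray(self.AC, dtype=float)
        self.PC = np.asarray(self.PC, dtype=float)
        self.validate()

    @property
    def has_extended(self) -> bool:
        return self.CC_top is not None and self.OF_ventral is not None

    def validate(self) -> None:
        if not (self.A > self.AC[1] > self.PC[1] > self.P):
            raise ValueError("landmark ordering violation on the anterior axis "
                             f"(need A > AC_y > PC_y > P, got {self.A}, {self.AC[1]}, "
                             f"{self.PC[1]}, {self.P})")
        if not self.L < self.R:
            raise ValueError("landmark ordering violation: L must be < R")
        if not self.I < self.S:
            raise ValueError("landmark ordering violation: I must be < S")
        if self.has_extended:
            if not (self.I < self.OF_ventral < self.AC[2] < self.CC_top < self.S):
                raise ValueError("landmark ordering violation on the vertical axis "
                                 "(need I < OF_ventral < AC_z < CC_top < S)")

    @classmethod
    def from_space(cls, landmarks: dict) -> "LandmarkSet":
        return cls(
            AC=np.asarray(landmarks["AC"]), PC=np.asarray(landmarks["PC"]),
            L=landmarks["L"], R=landmarks["R"], A=landmarks["A"], P=landmarks["P"],
            S=landmarks["S"], I=landmarks["I"],
            CC_top=landmarks.get("CC_top"), OF_ventral=landmarks.get("OF_ventral"),
        )


@dataclass
class EllipseFit:
    center: np.ndarray        # (u, v) mm in MSP-plane coordinates
    a: float                  # semi-major, mm
    b: float                  # semi-minor, mm
    orientation: float        # radians, major-axis direction in the (u, v) plane
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse axes must satisfy a >= b > 0")


@dataclass
class MipImage:
    """A MIP slab resampled into MSP-plane coordinates."""

    image: np.ndarray          # (nu, nv)
    us: np.ndarray             # mm along u_dir
    vs: np.ndarray             # mm along v_dir
    plane_origin: np.ndarray   # world point at (u, v) = (0, 0)
    u_dir: np.ndarray          # world unit vector, ~anterior
    v_dir: np.ndarray          # world unit vector, ~superior
    normal: np.ndarray         # plane normal

    def plane_to_world(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        return self.plane_origin + uv[:, :1] * self.u_dir + uv[:, 1:2] * self.v_dir


def plane_frame(msp: Plane) -> tuple[np.ndarray, np.ndarray]:
    """In-plane unit vectors (u ~ anterior, v ~ superior) for an MSP."""
    n = msp.normal
    ey = np.array([0.0, 1.0, 0.0])
    u = ey - np.dot(n, ey) * n
    if np.linalg.norm(u) < 1e-6:
        raise ValueError("degenerate MSP orientation")
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    if v[2] < 0:  # flip both to keep (n, u, v) right-handed, v superior
        u, v = -u, -v
    return u, v


def mip_slab(
    volume: Volume3D,
    msp: Plane,
    width_mm: float,
    sample_spacing: float | None = None,
) -> MipImage:
    """Maximum intensity projection over a sagittal slab around the MSP."""
    if width_mm <= 0:
        raise ValueError("width_mm must be positive")
    n = msp.normal
    u_dir, v_dir = plane_frame(msp)
    c = volume.world_center()
    o = c - (np.dot(n, c) - msp.offset) * n

    sp = sample_spacing or float(min(volume.spacing))
    half_ext = 0.5 * float(
        np.linalg.norm((np.asarray(volume.shape) - 1) * np.asarray(volume.spacing))
    )
    us = np.arange(-half_ext, half_ext + sp, sp)
    vs = np.arange(-half_ext, half_ext + sp, sp)
    n_w = max(1, int(round(width_mm / sp)))
    ws = (np.arange(n_w) - (n_w - 1) / 2.0) * sp if n_w > 1 else np.array([0.0])

    uu, vv = np.meshgrid(us, vs, indexing="ij")
    base = (o[None, None, :]
            + uu[:, :, None] * u_dir[None, None, :]
            + vv[:, :, None] * v_dir[None, None, :])
    # verify the slab intersects the volume at all
    mins = volume.index_to_world([0, 0, 0])
    maxs = volume.index_to_world(np.asarray(volume.shape) - 1)
    if np.any(o < mins - 1.0) or np.any(o > maxs + 1.0):
        raise ValueError("slab lies outside the volume")

    out = np.full(uu.shape, -np.inf)
    for w in ws:
        pts = base + w * n[None, None, :]
        idx = volume.world_to_index(pts.reshape(-1, 3)).T
        vals = ndimage.map_coordinates(
            volume.data.astype(float), idx, order=1, mode="constant", cval=0.0
        ).reshape(uu.shape)
        out = np.maximum(out, vals)
    return MipImage(out, us, vs, o, u_dir, v_dir, n)


def cortex_outline(
    mip: MipImage,
    lower_threshold: float = 70.0,
    upper_threshold: float = 200.0,
    n_fiducials: int = 128,
) -> np.ndarray:
    """Ordered fiducial points (mm, plane coords) on the cortex boundary.

    Takes the largest connected component inside the threshold band (which
    drops both background/CSF and any bright skull ring), fills holes, and
    subsamples its boundary.
    """
    mask = (mip.image > lower_threshold) & (mip.image < upper_threshold)
    # any bright (bone-valued) ring is excised together with its 2-pixel
    # partial-volume halo, which otherwise bridges the cortex to the skull
    bright = mip.image >= upper_threshold
    if bright.any():
        mask &= ~ndimage.binary_dilation(bright, iterations=2)
    lab = cc_label(mask)
    if lab.max() == 0:
        raise ValueError("no cortex component above threshold")
    largest = int(np.argmax(np.bincount(lab.ravel())[1:])) + 1
    comp = ndimage.binary_fill_holes(lab == largest)
    # sub-pixel boundary: level set of the image restricted to the component
    # (bright skull, if any, is zeroed so the contour cannot bridge to it)
    img = np.where(ndimage.binary_dilation(comp), mip.image, 0.0)
    img = np.where(img >= upper_threshold, 0.0, img)
    contours = find_contours(img, lower_threshold)
    if not contours:
        contours = find_contours(comp.astype(float), 0.5)
    if not contours:
        raise ValueError("no cortex outline found")
    pts_idx = max(contours, key=len)
    step = max(1, len(pts_idx) // max(n_fiducials, 64))
    pts_idx = pts_idx[::step]
    su = mip.us[1] - mip.us[0]
    sv = mip.vs[1] - mip.vs[0]
    return np.column_stack([
        mip.us[0] + pts_idx[:, 0] * su,
        mip.vs[0] + pts_idx[:, 1] * sv,
    ])


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Least-squares conic fit of an ellipse to boundary points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise ValueError("need at least 6 (u, v) points")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError(f"ellipse fit failed: {model}")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if a < b:
        a, b = b, a
        theta += np.pi / 2.0
    if a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse fit")
    theta = (theta + np.pi / 2.0) % np.pi - np.pi / 2.0
    rms = float(np.sqrt(np.mean(model.residuals(pts) ** 2)))
    return EllipseFit(np.array([xc, yc]), float(a), float(b), float(theta), rms)


def landmarks_from_ellipse(
    fit: EllipseFit,
    fractions: dict | None = None,
    lr: tuple[float, float] | None = None,
    extended: bool = True,
) -> LandmarkSet:
    """Statistical landmarks from the fitted cortex ellipse.

    Coordinates are expressed in the *ellipse-centered aligned frame*: y runs
    along the major axis (anterior positive), z along the minor axis
    (superior positive), x across the MSP with the plane at x = 0.  The
    default fractions are the normalized-space calibration constants; ``lr``
    overrides the lateral extents with measured ones (mm, same frame).
    """
    f = fractions or nspace.ELLIPSE_LANDMARK_FRACTIONS
    a, b = fit.a, fit.b
    ac = np.array([0.0, f["ac_major"] * a, f["ac_minor"] * b])
    pc = np.array([0.0, f["pc_major"] * a, f["pc_minor"] * b])
    if lr is None:
        half_w = f["half_width_major"] * a
        lr = (-half_w, half_w)
    return LandmarkSet(
        AC=ac, PC=pc, L=lr[0], R=lr[1], A=a, P=-a, S=b, I=-b,
        CC_top=f["cc_top_minor"] * b if extended else None,
        OF_ventral=f["of_ventral_minor"] * b if extended else None,
    )


def frame_from_fit(msp: Plane, mip: MipImage, fit: EllipseFit) -> tuple[np.ndarray, np.ndarray]:
    """World rotation/origin of the ellipse-centered aligned frame.

    Columns of the rotation are the frame's x (MSP normal), y (ellipse major
    axis, anterior) and z (minor axis, superior) directions in world space.
    """
    cth, sth = np.cos(fit.orientation), np.sin(fit.orientation)
    y_dir = cth * mip.u_dir + sth * mip.v_dir
    if y_dir[1] < 0:
        y_dir = -y_dir
    z_dir = np.cross(msp.normal, y_dir)
    if z_dir[2] < 0:
        z_dir = -z_dir
        # keep right-handedness by flipping the normal column instead
    x_dir = np.cross(y_dir, z_dir)
    rot = np.column_stack([x_dir, y_dir, z_dir])
    origin = mip.plane_to_world(fit.center)[0]
    return rot, origin


# --------------------------------------------------------------------------
# Piecewise-linear transform
# --------------------------------------------------------------------------

@dataclass
class Region:
    """One cuboid of the partition with its per-axis affine map."""

    src_lo: np.ndarray
    src_hi: np.ndarray
    tgt_lo: np.ndarray
    scale: np.ndarray

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return self.tgt_lo + (pts - self.src_lo) * self.scale


def _axis_breaks(lms: LandmarkSet, extended: bool) -> list[np.ndarray]:
    bx = np.array([lms.L, lms.AC[0], lms.R])
    by = np.array([lms.P, lms.PC[1], lms.AC[1], lms.A])
    if extended:
        bz = np.array([lms.I, lms.OF_ventral, lms.AC[2], lms.CC_top, lms.S])
    else:
        bz = np.array([lms.I, lms.AC[2], lms.S])
    for br in (bx, by, bz):
        if np.any(np.diff(br) <= 0):
            raise ValueError("landmark ordering violation in breakpoints")
    return [bx, by, bz]


@dataclass
class PiecewiseLinearTransform:
    """Landmark-defined cuboid partition with per-region scale factors.

    Maps source (atlas) aligned coordinates to target aligned coordinates by
    independent per-axis piecewise-linear interpolation between landmark
    breakpoints, then into world space through the target frame (rotation
    ``frame_rot`` and origin ``frame_origin``).  Half-open region membership
    ``[lo, hi)`` makes boundary evaluation unambiguous, and the shared
    breakpoints make the map continuous across region faces.
    """

    source_landmarks: LandmarkSet
    target_landmarks: LandmarkSet
    extended: bool = False
    frame_rot: np.ndarray = field(default_factory=lambda: np.eye(3))
    frame_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.extended and not (
            self.source_landmarks.has_extended and self.target_landmarks.has_extended
        ):
            raise ValueError("extended transform requires CC_top and OF_ventral "
                             "in both landmark sets")
        self._src_breaks = _axis_breaks(self.source_landmarks, self.extended)
        self._tgt_breaks = _axis_breaks(self.target_landmarks, self.extended)
        self.frame_rot = np.asarray(self.frame_rot, dtype=float)
        self.frame_origin = np.asarray(self.frame_origin, dtype=float)

    # -- bookkeeping --------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return int(np.prod([len(b) - 1 for b in self._src_breaks]))

    @property
    def dof(self) -> int:
        n_scales = sum(len(b) - 1 for b in self._src_breaks)
        return n_scales + 3 + 3  # scales + translations + orientations

    @property
    def regions(self) -> list[Region]:
        out = []
        bs, bt = self._src_breaks, self._tgt_breaks
        for i in range(len(bs[0]) - 1):
            for j in range(len(bs[1]) - 1):
                for k in range(len(bs[2]) - 1):
                    lo = np.array([bs[0][i], bs[1][j], bs[2][k]])
                    hi = np.array([bs[0][i + 1], bs[1][j + 1], bs[2][k + 1]])
                    tlo = np.array([bt[0][i], bt[1][j], bt[2][k]])
                    thi = np.array([bt[0][i + 1], bt[1][j + 1], bt[2][k + 1]])
                    out.append(Region(lo, hi, tlo, (thi - tlo) / (hi - lo)))
        return out

    # -- evaluation ---------------------------------------------------------
    def _pwl(self, pts: np.ndarray, src, tgt, warn: bool = True) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        lo = np.array([b[0] for b in src])
        hi = np.array([b[-1] for b in src])
        outside = (pts < lo) | (pts > hi)
        if warn and outside.any():
            warnings.warn(
                f"{int(outside.any(axis=1).sum())} point(s) outside the landmark "
                "bounding box were clamped", stacklevel=3,
            )
        out = np.empty_like(pts)
        for k in range(3):
            out[:, k] = np.interp(pts[:, k], src[k], tgt[k])
        return out

    def apply(self, points: np.ndarray, warn: bool = True) -> np.ndarray:
        """Source aligned coordinates -> target world coordinates."""
        aligned = self._pwl(points, self._src_breaks, self._tgt_breaks, warn)
        return self.frame_origin + aligned @ self.frame_rot.T

    def inverse_apply(self, points_world: np.ndarray, warn: bool = False) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_world, dtype=float))
        aligned = (pts - self.frame_origin) @ self.frame_rot
        return self._pwl(aligned, self._tgt_breaks, self._src_breaks, warn)

    def to_dict(self) -> dict:
        def lm(l: LandmarkSet) -> dict:
            d = {"AC": l.AC.tolist(), "PC": l.PC.tolist(), "L": l.L, "R": l.R,
                 "A": l.A, "P": l.P, "S": l.S, "I": l.I}
            if l.has_extended:
                d["CC_top"] = l.CC_top
                d["OF_ventral"] = l.OF_ventral
            return d
        return {
            "source_landmarks": lm(self.source_landmarks),
            "target_landmarks": lm(self.target_landmarks),
            "extended": self.extended,
            "frame_rot": self.frame_rot.tolist(),
            "frame_origin": self.frame_origin.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseLinearTransform":
        def lm(x: dict) -> LandmarkSet:
            return LandmarkSet(
                AC=np.asarray(x["AC"]), PC=np.asarray(x["PC"]), L=x["L"], R=x["R"],
                A=x["A"], P=x["P"], S=x["S"], I=x["I"],
                CC_top=x.get("CC_top"), OF_ventral=x.get("OF_ventral"),
            )
        return cls(lm(d["source_landmarks"]), lm(d["target_landmarks"]),
                   d["extended"], np.asarray(d["frame_rot"]), np.asarray(d["frame_origin"]))


def build_transform(
    source: LandmarkSet,
    target: LandmarkSet,
    extended: bool = False,
    frame_rot: np.ndarray | None = None,
    frame_origin: np.ndarray | None = None,
) -> PiecewiseLinearTransform:
    return PiecewiseLinearTransform(
        source, target, extended,
        np.eye(3) if frame_rot is None else frame_rot,
        np.zeros(3) if frame_origin is None else frame_origin,
    )


def apply_to_points(t: PiecewiseLinearTransform, points: np.ndarray) -> np.ndarray:
    return t.apply(points)


def apply_to_labels(
    t: PiecewiseLinearTransform, labels: Volume3D, out_grid: Volume3D
) -> Volume3D:
    """Resample a source-space label volume onto the target grid (nearest)."""
    nx, ny, nz = out_grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    world = out_grid.index_to_world(
        np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    )
    src = t.inverse_apply(world, warn=False)
    idx = np.rint(labels.world_to_index(src)).astype(int)
    valid = np.all((idx >= 0) & (idx < np.asarray(labels.shape)), axis=1)
    out = np.zeros(nx * ny * nz, dtype=labels.data.dtype)
    iv = idx[valid]
    out[valid] = labels.data[iv[:, 0], iv[:, 1], iv[:, 2]]
    return out_grid.like(out.reshape(nx, ny, nz))


# --------------------------------------------------------------------------
# Full individualization chain
# --------------------------------------------------------------------------

def individualize_atlas(
    bundle,
    scan: Volume3D,
    method: Literal["ellipse", "landmarks-given"] = "ellipse",
    landmarks: LandmarkSet | None = None,
    frame_rot: np.ndarray | None = None,
    frame_origin: np.ndarray | None = None,
    tilted: bool = False,
    extended: bool = False,
    msp_params: MspParams | None = None,
    mip_width_mm: float = 10.0,
    outline_thresholds: tuple[float, float] = (70.0, 200.0),
    measure_lr: bool = True,
):
    """Map the atlas bundle onto a scan; returns (bundle on scan grid, transform).

    The ellipse path runs the full statistical chain: MSP -> MIP slab ->
    cortex outline -> ellipse fit -> landmarks; the landmarks-given path
    accepts externally supplied landmarks in an aligned frame.
    """
    from .atlas import AtlasBundle  # local import to avoid a cycle

    src_lms = LandmarkSet.from_space(bundle.space.landmarks)
    if method == "landmarks-given":
        if landmarks is None:
            raise ValueError("landmarks-given method requires landmarks")
        rot = np.eye(3) if frame_rot is None else np.asarray(frame_rot)
        org = np.zeros(3) if frame_origin is None else np.asarray(frame_origin)
        transform = PiecewiseLinearTransform(src_lms, landmarks, extended, rot, org)
    elif method == "ellipse":
        transform = estimate_scan_transform(
            scan, src_lms, tilted=tilted, extended=extended, msp_params=msp_params,
            mip_width_mm=mip_width_mm, outline_thresholds=outline_thresholds,
            measure_lr=measure_lr,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    warped = AtlasBundle(
        anatomy=apply_to_labels(transform, bundle.anatomy, scan),
        territories=apply_to_labels(transform, bundle.territories, scan),
        ventricle_template=apply_to_labels(transform, bundle.ventricle_template, scan),
        legend=bundle.legend,
        space=bundle.space,
        validate_grids=False,
    )
    return warped, transform


def estimate_scan_transform(
    scan: Volume3D,
    source_landmarks: LandmarkSet,
    tilted: bool = False,
    extended: bool = False,
    msp_params: MspParams | None = None,
    mip_width_mm: float = 10.0,
    outline_thresholds: tuple[float, float] = (70.0, 200.0),
    measure_lr: bool = True,
) -> PiecewiseLinearTransform:
    """Run the ellipse chain on a scan and return the atlas->scan transform."""
    stage = "msp"
    try:
        msp = extract_msp_tilted(scan, msp_params) if tilted else extract_msp(scan, msp_params)
        stage = "mip_slab"
        mip = mip_slab(scan, msp, mip_width_mm)
        stage = "cortex_outline"
        pts = cortex_outline(mip, *outline_thresholds)
        stage = "fit_ellipse"
        fit = fit_ellipse(pts)
        stage = "landmarks_from_ellipse"
        rot, org = frame_from_fit(msp, mip, fit)
        lr = _measure_lateral_extents(scan, msp, fit, mip) if measure_lr else None
        if lr is not None:
            # re-center the midplane on the measured lateral extents: the KL
            # plane can sit a partial-volume voxel off the anatomical midline
            mid = 0.5 * (lr[0] + lr[1])
            org = org + rot[:, 0] * mid
            lr = (lr[0] - mid, lr[1] - mid)
        scan_lms = landmarks_from_ellipse(fit, lr=lr)
    except ValueError as e:
        raise ValueError(f"atlas-to-scan mapping failed at stage {stage}: {e}") from e
    return PiecewiseLinearTransform(source_landmarks, scan_lms, extended, rot, org)


def _measure_lateral_extents(scan, msp, fit, mip) -> tuple[float, float] | None:
    """L/R cortical extents from the 3D brain mask at the AC-PC axial level."""
    from .lesionseg import extract_brain_ct

    try:
        brain = extract_brain_ct(scan)
    except ValueError:
        return None
    rot, org = frame_from_fit(msp, mip, fit)
    idx = np.argwhere(brain.data > 0)
    if idx.shape[0] == 0:
        return None
    world = brain.index_to_world(idx)
    aligned = (world - org) @ rot
    f = nspace.ELLIPSE_LANDMARK_FRACTIONS
    ac_z = f["ac_minor"] * fit.b
    slab = np.abs(aligned[:, 2] - ac_z) <= 4.0
    if slab.sum() < 50:
        return None
    xs = aligned[slab, 0]
    return float(np.percentile(xs, 0.2)), float(np.percentile(xs, 99.8))
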