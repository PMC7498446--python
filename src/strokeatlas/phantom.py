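"""Procedural head phantoms and synthetic stroke cohorts.

The phantom is a left-right symmetric brain ellipsoid (gray-matter shell over
a white-matter core) inside a high-intensity skull shell, with CSF in the
interhemispheric fissure, the subarachnoid gap and two lateral ventricles.
Intensities use a CT-like 8-bit scale.  The generator applies, in order:
spherical hypo-/hyperdense lesions, a polynomial multiplicative bias field,
rigid head rotation (by linear resampling about the grid center; ground truth
is transformed analytically), additive Gaussian noise, and axial slice-
thickness resampling.

Cohorts couple lesion geometry to clinical outcome variables (mRS-, BI- and
NIHSS-like scores) so that probabilistic-atlas prediction has a recoverable
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from . import space
from .mapping import LandmarkSet
from .volume import Plane, Volume3D, rotation_matrix, rotate_volume

DEFAULT_TISSUE_MEANS = {
    "air": 0.0,
    "csf": 30.0,
    "white": 90.0,
    "gray": 110.0,
    "skull": 255.0,
}
DEFAULT_LESION_MEANS = {"hypodense": 72.0, "hyperdense": 190.0}

TISSUE_CODES = {"air": 0, "csf": 1, "gray": 2, "white": 3, "skull": 4}


@dataclass(frozen=True)
class LesionSpec:
    """A spherical lesion to insert into the phantom brain."""

    side: Literal["left", "right"]
    center_mm: tuple[float, float, float]
    radius_mm: float
    contrast: Literal["hypodense", "hyperdense"] = "hypodense"
    territory_hint: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown lesion side {self.side!r}")
        if self.contrast not in ("hypodense", "hyperdense"):
            raise ValueError(f"unknown lesion contrast {self.contrast!r}")


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)  # yaw, pitch, roll
    noise_sd: float = 2.0
    inhomogeneity_pct: float = 0.0
    lesion_specs: tuple[LesionSpec, ...] = ()
    slice_thickness_mm: float | None = None
    seed: int = 0
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    lesion_means: dict = field(default_factory=lambda: dict(DEFAULT_LESION_MEANS))

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.inhomogeneity_pct < 0:
            raise ValueError("inhomogeneity_pct must be >= 0")
        if not all(np.isfinite(self.rotation_deg)):
            raise ValueError("rotation angles must be finite")
        if self.slice_thickness_mm is not None and self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")


@dataclass
class PhantomCase:
    """A generated scan plus every piece of ground truth needed to score it."""

    volume: Volume3D
    truth_msp: Plane
    truth_landmarks: LandmarkSet
    truth_frame: np.ndarray         # rotation matrix mapping aligned frame -> world
    truth_frame_origin: np.ndarray  # translation of that map (zero when unrotated)
    ventricle_mask: Volume3D
    lesion_mask: Volume3D
    tissue_labels: Volume3D
    brain_mask: Volume3D
    config: PhantomConfig


def _centered_origin(shape, spacing) -> tuple[float, float, float]:
    """Origin placing the canonical brain center at the grid center.

    World coordinates keep the AC at the origin; centering the brain (not
    the AC) in the grid leaves room for the posterior skull within the
    default field of view.
    """
    return tuple(
        float(c) - (n - 1) / 2.0 * s
        for c, n, s in zip(space.BRAIN_CENTER, shape, spacing)
    )


def _grid_world(shape, spacing):
    origin = _centered_origin(shape, spacing)
    return tuple(origin[k] + spacing[k] * np.arange(shape[k]) for k in range(3))


def _bias_field(xs, ys, zs, pct: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order polynomial multiplicative field with given peak-to-peak %."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    u = np.linspace(-1, 1, nx)[:, None, None]
    v = np.linspace(-1, 1, ny)[None, :, None]
    w = np.linspace(-1, 1, nz)[None, None, :]
    c = rng.uniform(-1, 1, size=6)
    f = c[0] * u + c[1] * v + c[2] * w + c[3] * u * v + c[4] * u * w + c[5] * v * w
    span = f.max() - f.min()
    if span == 0:
        return np.ones((nx, ny, nz))
    f = (f - f.min()) / span - 0.5  # [-0.5, 0.5]
    return 1.0 + f * (pct / 100.0)


def _resample_slices(vol: Volume3D, thickness_mm: float, reduce: str) -> Volume3D:
    """Merge axial slices into thick acquisition slices by block pooling."""
    sz = vol.spacing[2]
    factor = max(1, int(round(thickness_mm / sz)))
    if factor == 1:
        return vol
    nz = (vol.shape[2] // factor) * factor
    data = vol.data[:, :, :nz]
    blocks = data.reshape(vol.shape[0], vol.shape[1], nz // factor, factor)
    if reduce == "mean":
        pooled = blocks.mean(axis=3)
    elif reduce == "majority":
        pooled = (blocks.mean(axis=3) >= 0.5).astype(vol.data.dtype)
    elif reduce == "center":
        pooled = blocks[:, :, :, factor // 2]
    else:  # pragma: no cover
        raise ValueError(reduce)
    new_spacing = (vol.spacing[0], vol.spacing[1], sz * factor)
    new_origin = (vol.origin[0], vol.origin[1], vol.origin[2] + (factor - 1) / 2.0 * sz)
    return Volume3D(pooled, new_spacing, new_origin)


def make_head_phantom(config: PhantomConfig) -> PhantomCase:
    """Generate a ground-truthed CT-style head phantom.

    Deterministic for a fixed ``config.seed``.  Ground truth (midsagittal
    plane, landmarks) is transformed analytically by the configured rotation,
    not by resampling.
    """
    rng = np.random.default_rng(config.seed)
    shape, spacing = tuple(config.grid_shape), tuple(config.spacing_mm)
    xs, ys, zs = _grid_world(shape, spacing)
    tm = config.tissue_means

    brain = space.brain_ellipsoid_mask(xs, ys, zs)
    inner_skull = space.ellipsoid_mask(
        xs, ys, zs, space.BRAIN_CENTER, space.BRAIN_SEMIAXES + 2.0
    )
    outer_skull = space.ellipsoid_mask(
        xs, ys, zs, space.BRAIN_CENTER, space.BRAIN_SEMIAXES + 7.0
    )
    skull = outer_skull & ~inner_skull
    gap_csf = inner_skull & ~brain
    white = space.ellipsoid_mask(
        xs, ys, zs, space.BRAIN_CENTER, space.BRAIN_SEMIAXES * 0.78
    )
    fissure = brain & (np.abs(xs)[:, None, None] < space.FISSURE_HALF_WIDTH)
    vent = np.zeros(shape, dtype=bool)
    for c in space.VENTRICLE_CENTERS:
        vent |= space.ellipsoid_mask(xs, ys, zs, c, space.VENTRICLE_SEMIAXES)
    vent &= brain

    labels = np.zeros(shape, dtype=np.uint8)
    labels[brain & ~white] = TISSUE_CODES["gray"]
    labels[brain & white] = TISSUE_CODES["white"]
    labels[gap_csf | fissure | vent] = TISSUE_CODES["csf"]
    labels[skull] = TISSUE_CODES["skull"]

    intensity = np.full(shape, tm["air"], dtype=float)
    for name in ("gray", "white", "csf", "skull"):
        intensity[labels == TISSUE_CODES[name]] = tm[name]

    lesion = np.zeros(shape, dtype=bool)
    for i, spec in enumerate(config.lesion_specs):
        c = np.asarray(spec.center_mm, dtype=float)
        ball = space.ellipsoid_mask(xs, ys, zs, c, np.full(3, spec.radius_mm))
        if not ball.any() or not (ball <= brain).all():
            raise ValueError(f"lesion {i} extends outside the brain")
        expect_left = spec.side == "left"
        if (c[0] < 0) != expect_left:
            raise ValueError(f"lesion {i}: center x={c[0]} inconsistent with side {spec.side!r}")
        intensity[ball] = config.lesion_means[spec.contrast]
        lesion |= ball

    if config.inhomogeneity_pct > 0:
        intensity *= _bias_field(xs, ys, zs, config.inhomogeneity_pct, rng)

    origin = _centered_origin(shape, spacing)
    vol = Volume3D(intensity, spacing, origin)
    rot = rotation_matrix(*config.rotation_deg)
    rot_center = space.BRAIN_CENTER
    rotated = any(abs(a) > 1e-12 for a in config.rotation_deg)
    if rotated:
        vol = rotate_volume(vol, rot, center_world=rot_center, order=1, cval=tm["air"])

        def rot_mask(m):
            v = rotate_volume(
                Volume3D(m.astype(float), spacing, origin), rot,
                center_world=rot_center, order=0,
            )
            return Volume3D(v.data.astype(np.uint8), spacing, origin)

        vent_v = rot_mask(vent)
        lesion_v = rot_mask(lesion)
        brain_v = rot_mask(brain)
        labels_v = rotate_volume(
            Volume3D(labels.astype(float), spacing, origin), rot,
            center_world=np.zeros(3), order=0,
        )
        labels_v = Volume3D(labels_v.data.astype(np.uint8), spacing, origin)
    else:
        vent_v = Volume3D(vent.astype(np.uint8), spacing, origin)
        lesion_v = Volume3D(lesion.astype(np.uint8), spacing, origin)
        brain_v = Volume3D(brain.astype(np.uint8), spacing, origin)
        labels_v = Volume3D(labels, spacing, origin)

    if config.noise_sd > 0:
        vol = vol.like(vol.data + rng.normal(0.0, config.noise_sd, size=shape))
    vol = vol.like(np.clip(vol.data, 0.0, 255.0))

    if config.slice_thickness_mm is not None:
        vol = _resample_slices(vol, config.slice_thickness_mm, "mean")
        vent_v = _resample_slices(vent_v, config.slice_thickness_mm, "majority")
        lesion_v = _resample_slices(lesion_v, config.slice_thickness_mm, "majority")
        brain_v = _resample_slices(brain_v, config.slice_thickness_mm, "majority")
        labels_v = _resample_slices(labels_v, config.slice_thickness_mm, "center")

    truth_msp = Plane.from_point_normal(rot_center, rot @ np.array([1.0, 0.0, 0.0]))
    truth_landmarks = LandmarkSet(
        AC=space.AC.copy(), PC=space.PC.copy(),
        L=space.CORTEX_L, R=space.CORTEX_R,
        A=space.CORTEX_A, P=space.CORTEX_P,
        S=space.CORTEX_S, I=space.CORTEX_I,
        CC_top=space.CC_TOP, OF_ventral=space.OF_VENTRAL,
    )
    return PhantomCase(
        volume=vol, truth_msp=truth_msp, truth_landmarks=truth_landmarks,
        truth_frame=rot, truth_frame_origin=rot_center - rot @ rot_center,
        ventricle_mask=vent_v, lesion_mask=lesion_v,
        tissue_labels=labels_v, brain_mask=brain_v, config=config,
    )


# MR tissue means: rows are modalities, values per tissue.  WMH lesions are
# bright on T2/PD and mildly hypointense on T1, as in small-vessel disease.
DEFAULT_MR_MEANS = {
    "t1": {"air": 0, "csf": 40, "white": 160, "gray": 110, "skull": 20, "wmh": 130},
    "t2": {"air": 0, "csf": 200, "white": 70, "gray": 110, "skull": 20, "wmh": 210},
    "pd": {"air": 0, "csf": 140, "white": 100, "gray": 130, "skull": 20, "wmh": 200},
}


def make_mr_head_phantom(
    config: PhantomConfig,
    wmh_specs: Sequence[LesionSpec] = (),
    mr_means: dict | None = None,
) -> dict:
    """Co-registered T1/T2/PD phantoms with optional WMH blobs.

    Returns a dict with the three volumes, the WMH truth mask, the ventricle
    mask and the brain mask, all on the same grid.
    """
    means = mr_means or DEFAULT_MR_MEANS
    base = make_head_phantom(replace(config, lesion_specs=(), noise_sd=0.0))
    shape, spacing = tuple(config.grid_shape), tuple(config.spacing_mm)
    xs, ys, zs = _grid_world(shape, spacing)
    labels = base.tissue_labels.data
    wmh = np.zeros(shape, dtype=bool)
    brain = base.brain_mask.data.astype(bool)
    for i, spec in enumerate(wmh_specs):
        ball = space.ellipsoid_mask(
            xs, ys, zs, np.asarray(spec.center_mm, dtype=float), np.full(3, spec.radius_mm)
        )
        if not ball.any() or not (ball <= brain).all():
            raise ValueError(f"WMH blob {i} extends outside the brain")
        wmh |= ball

    rng = np.random.default_rng(config.seed)
    out = {}
    code_to_name = {v: k for k, v in TISSUE_CODES.items()}
    for mod in ("t1", "t2", "pd"):
        img = np.zeros(shape, dtype=float)
        for code, name in code_to_name.items():
            img[labels == code] = means[mod][name]
        img[wmh] = means[mod]["wmh"]
        if config.noise_sd > 0:
            img += rng.normal(0.0, config.noise_sd, size=shape)
        out[mod] = Volume3D(np.clip(img, 0, 255), spacing, base.volume.origin)
    out["wmh_mask"] = base.ventricle_mask.like(wmh.astype(np.uint8))
    out["ventricle_mask"] = base.ventricle_mask
    out["brain_mask"] = base.brain_mask
    return out


# --------------------------------------------------------------------------
# Synthetic cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeModel:
    """Couples an outcome variable to lesion geometry.

    ``linear`` models evaluate ``intercept + coeffs . centroid_mm`` at the
    lesion centroid (aligned-frame mm, AC origin); ``field`` models average a
    spatial weight volume over the lesion.  Gaussian noise with ``noise_sd``
    is added on top.
    """

    kind: Literal["linear", "field", "constant"] = "linear"
    intercept: float = 0.0
    coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    volume_coef: float = 0.0      # dependence on lesion volume (per ml)
    weight_field: Volume3D | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def evaluate(self, centroid_mm: np.ndarray, lesion_mask: Volume3D) -> float:
        vol_ml = float((lesion_mask.data > 0).sum()) * lesion_mask.voxel_volume_ml()
        if self.kind == "constant":
            return float(self.intercept)
        if self.kind == "linear":
            return float(self.intercept + np.dot(self.coeffs, centroid_mm)
                         + self.volume_coef * vol_ml)
        if self.kind == "field":
            assert self.weight_field is not None
            idx = np.argwhere(lesion_mask.data > 0)
            pts = lesion_mask.index_to_world(idx)
            return float(np.mean(self.weight_field.sample_world(pts))
                         + self.volume_coef * vol_ml)
        raise ValueError(self.kind)  # pragma: no cover


def default_couplings() -> dict[str, OutcomeModel]:
    """Plausible stroke-scale couplings on their clinical ranges.

    mRS (0-6) worsens toward larger, more lateral-posterior lesions; BI
    (0-100) mirrors it; NIHSS severity scales with lesion extent along the
    antero-posterior axis.
    """
    return {
        "mRS_day90": OutcomeModel("linear", 2.0, (0.0, -1.0 / 40.0, 0.0),
                                  volume_coef=0.05, noise_sd=0.3),
        "BI_day360": OutcomeModel("linear", 70.0, (0.0, 12.0 / 40.0, 0.0),
                                  volume_coef=-0.6, noise_sd=4.0),
        "NIHSS_admission": OutcomeModel("linear", 6.0, (0.0, -2.0 / 40.0, 0.0),
                                        volume_coef=0.25, noise_sd=1.0),
        "NIHSS_day7": OutcomeModel("linear", 4.0, (0.0, -2.0 / 40.0, 0.0),
                                   volume_coef=0.2, noise_sd=1.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = 32
    outcome_names: tuple[str, ...] = ("mRS_day90", "BI_day360", "NIHSS_admission")
    coupling: dict = field(default_factory=default_couplings)
    lesion_volume_range_ml: tuple[float, float] = (5.0, 40.0)
    seed: int = 0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not self.outcome_names:
            raise ValueError("outcome_names must not be empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.lesion_volume_range_ml
        if not (0 < lo <= hi):
            raise ValueError("lesion_volume_range_ml must be a positive interval")


def _sample_lesion(rng: np.random.Generator, spec: CohortSpec) -> LesionSpec:
    vol_ml = rng.uniform(*spec.lesion_volume_range_ml)
    radius = (3.0 * vol_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    margin = radius + 3.0
    semi = np.maximum(space.BRAIN_SEMIAXES - margin, 5.0)
    while True:
        u = rng.uniform(-1, 1, size=3)
        if np.sum(u**2) <= 1.0 and abs(u[0] * semi[0]) > radius * 0.3 + 2.0:
            break
    center = space.BRAIN_CENTER + u * semi
    side = "left" if center[0] < 0 else "right"
    return LesionSpec(side=side, center_mm=tuple(center), radius_mm=radius)


def make_cohort(spec: CohortSpec) -> list:
    """Generate a synthetic cohort of stroke cases with coupled outcomes."""
    from .lesionseg import contours_from_mask
    from .psa import CaseRecord

    rng = np.random.default_rng(spec.seed)
    missing = [n for n in spec.outcome_names if n not in spec.coupling]
    if missing:
        raise ValueError(f"no coupling model for outcomes: {missing}")

    cases = []
    for i in range(spec.n_cases):
        lesion = _sample_lesion(rng, spec)
        cfg = PhantomConfig(
            grid_shape=spec.grid_shape, spacing_mm=spec.spacing_mm,
            noise_sd=spec.noise_sd, lesion_specs=(lesion,),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case_phantom = make_head_phantom(cfg)
        mask = case_phantom.lesion_mask
        idx = np.argwhere(mask.data > 0)
        centroid = mask.index_to_world(idx).mean(axis=0)
        vol_ml = float(idx.shape[0]) * mask.voxel_volume_ml()

        variables = {"infarct_volume_ml": vol_ml}
        for name in spec.outcome_names:
            model = spec.coupling[name]
            noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
            variables[name] = model.evaluate(centroid, mask) + noise
        for name in ("NIHSS_admission", "NIHSS_day7"):
            if name not in variables and name in spec.coupling:
                model = spec.coupling[name]
                noise = rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0
                variables[name] = model.evaluate(centroid, mask) + noise

        cases.append(CaseRecord(
            case_id=f"case{i:04d}",
            scan=case_phantom.volume,
            lesion_contours=contours_from_mask(mask),
            variables=variables,
            truth_landmarks=case_phantom.truth_landmarks,
            truth_frame=case_phantom.truth_frame,
            truth_frame_origin=case_phantom.truth_frame_origin,
            meta={"centroid_mm": centroid, "lesion_spec": lesion},
        ))
    return cases
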