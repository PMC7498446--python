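"""Probabilistic stroke atlas (PSA): construction, prediction, evaluation.

A PSA volume aggregates, voxel by voxel, a clinical parameter (an outcome
scale, a laboratory value, ...) over the spatially normalized infarct ROIs
of a patient cohort (type-III ROI regime).  Prediction for a new patient
reads the statistics of the selected PSA volume inside the patient's
normalized infarct ROI (type-II regime).

The aggregation pseudocode divides the voxelwise parameter sums "by the
number of cases", which is ambiguous between the global case count and the
per-voxel count of contributing cases; both are implemented
(``mean_global_n`` and ``mean_coverage``), the latter being the default for
prediction because global-N division shrinks values toward zero wherever
coverage is sparse.  Six further registered schemes (median, trimmed mean,
min, max and two size-weighted means) support multi-scheme designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import space as nspace
from .atlas import make_space
from .lesionseg import ContourSet, mask_from_contours
from .mapping import LandmarkSet, PiecewiseLinearTransform, build_transform, estimate_scan_transform
from .volume import Volume3D


@dataclass
class CaseRecord:
    """One patient: scan, lesion contours, clinical variables."""

    case_id: str
    scan: Volume3D
    lesion_contours: ContourSet
    variables: dict[str, float]
    truth_landmarks: LandmarkSet | None = None
    truth_frame: np.ndarray | None = None
    truth_frame_origin: np.ndarray | None = None
    transform: PiecewiseLinearTransform | None = None  # lazily computed
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lesion_contours.is_empty():
            raise ValueError(f"case {self.case_id}: empty lesion contours")

    def lesion_mask(self) -> Volume3D:
        return mask_from_contours(self.lesion_contours, self.scan)


@dataclass
class PsaMap:
    """Aggregated parameter volume with per-voxel coverage counts."""

    parameter: str
    aggregate: Volume3D
    coverage: Volume3D
    n_cases: int
    scheme: str
    sum_values: np.ndarray | None = None  # retained for incremental updates

    def __post_init__(self) -> None:
        cov = self.coverage.data
        if cov.max() > self.n_cases:
            raise ValueError("coverage exceeds the number of cases")
        if np.any((cov == 0) & (self.aggregate.data != 0)):
            raise ValueError("aggregate must be 0 where coverage is 0")


@dataclass
class PsaDesign:
    """A multi-instance evaluation design (schemes x selection ranges)."""

    n_aggregations: int = 8
    selection_range_counts: tuple[int, ...] = (4, 4, 4)
    outcome_parameters: tuple[str, ...] = ()
    n_cases: int = 128

    def __post_init__(self) -> None:
        if self.n_aggregations < 1 or self.n_cases < 1:
            raise ValueError("design counts must be >= 1")
        if any(c < 1 for c in self.selection_range_counts):
            raise ValueError("range counts must be >= 1")


@dataclass
class PredictionResult:
    parameter: str
    mean: float
    sd: float
    p25: float
    p50: float
    p75: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (self.p25 <= self.p50 <= self.p75):
            raise ValueError("percentiles must be ordered")
        if self.n_voxels <= 0:
            raise ValueError("prediction read no voxels")


def default_psa_space(resolution_mm: float = 2.0) -> nspace.NormalizedSpace:
    return make_space(resolution_mm)


def _space_grid(space: nspace.NormalizedSpace) -> Volume3D:
    return Volume3D(np.zeros(space.shape, dtype=np.uint8), space.spacing, space.origin)


def case_transform(
    case: CaseRecord,
    space: nspace.NormalizedSpace,
    method: str = "landmarks-given",
    **kwargs,
) -> PiecewiseLinearTransform:
    """Atlas-space -> scan transform for a case (cached on the record)."""
    if case.transform is not None:
        return case.transform
    src = LandmarkSet.from_space(space.landmarks)
    if method == "landmarks-given":
        if case.truth_landmarks is None:
            raise ValueError(f"case {case.case_id}: no stored landmarks")
        frame = case.truth_frame if case.truth_frame is not None else np.eye(3)
        origin = case.truth_frame_origin if case.truth_frame_origin is not None else np.zeros(3)
        t = build_transform(src, case.truth_landmarks, frame_rot=frame, frame_origin=origin)
    elif method == "ellipse":
        t = estimate_scan_transform(case.scan, src, **kwargs)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    case.transform = t
    return t


def normalize_case(
    case: CaseRecord,
    space: nspace.NormalizedSpace,
    method: str = "landmarks-given",
    **kwargs,
) -> Volume3D:
    """Spatially normalize the case's lesion ROI into PSA space.

    The lesion contours are rasterized on the scan grid, then pulled back
    through the individualization transform: each PSA-space voxel reads the
    scan-space mask at its mapped position (nearest neighbor).
    """
    t = case_transform(case, space, method, **kwargs)
    mask = case.lesion_mask()
    grid = _space_grid(space)
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    world = grid.index_to_world(
        np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    )
    scan_pts = t.apply(world, warn=False)
    idx = np.rint(mask.world_to_index(scan_pts)).astype(int)
    valid = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    out = np.zeros(nx * ny * nz, dtype=np.uint8)
    iv = idx[valid]
    out[valid] = mask.data[iv[:, 0], iv[:, 1], iv[:, 2]]
    return grid.like(out.reshape(nx, ny, nz))


def _normalized_masks(cases, space, method, **kwargs) -> list[np.ndarray]:
    key = ("psa_mask", space.shape, space.spacing, space.origin, method)
    out = []
    for c in cases:
        cached = c.meta.get(key)
        if cached is None:
            cached = normalize_case(c, space, method, **kwargs).data.astype(bool)
            c.meta[key] = cached
        out.append(cached)
    return out


PSA_SCHEMES = (
    "mean_global_n", "mean_coverage", "median", "trimmed_mean",
    "min", "max", "volume_weighted_mean", "inverse_volume_weighted_mean",
)


def build_psa(
    cases: list[CaseRecord],
    parameter: str,
    scheme: str = "mean_coverage",
    space: nspace.NormalizedSpace | None = None,
    method: str = "landmarks-given",
    **kwargs,
) -> PsaMap:
    """Aggregate one clinical parameter over the normalized cohort ROIs."""
    if not cases:
        raise ValueError("need at least one case")
    if scheme not in PSA_SCHEMES:
        raise ValueError(f"unknown aggregation scheme {scheme!r}; "
                         f"registered: {', '.join(PSA_SCHEMES)}")
    for c in cases:
        if parameter not in c.variables:
            raise ValueError(f"case {c.case_id} is missing parameter {parameter!r}")
    space = space or default_psa_space()
    masks = _normalized_masks(cases, space, method, **kwargs)
    values = np.array([float(c.variables[parameter]) for c in cases])
    n = len(cases)

    coverage = np.zeros(space.shape, dtype=np.int32)
    for m in masks:
        coverage += m
    grid = _space_grid(space)
    cov_vol = Volume3D(coverage, space.spacing, space.origin)

    sum_values = None
    if scheme in ("mean_global_n", "mean_coverage"):
        s = np.zeros(space.shape, dtype=float)
        for m, v in zip(masks, values):
            s += m * v
        sum_values = s
        if scheme == "mean_global_n":
            agg = s / n
        else:
            agg = np.divide(s, coverage, out=np.zeros_like(s), where=coverage > 0)
    elif scheme in ("volume_weighted_mean", "inverse_volume_weighted_mean"):
        vols = np.array([m.sum() * np.prod(space.spacing) / 1000.0 for m in masks])
        w = vols if scheme == "volume_weighted_mean" else 1.0 / np.maximum(vols, 1e-9)
        num = np.zeros(space.shape, dtype=float)
        den = np.zeros(space.shape, dtype=float)
        for m, v, wi in zip(masks, values, w):
            num += m * (wi * v)
            den += m * wi
        agg = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    else:
        # order statistics over the covering cases, on the coverage union only
        union = coverage > 0
        flat = np.flatnonzero(union.ravel())
        stack = np.full((n, flat.size), np.nan)
        for r, (m, v) in enumerate(zip(masks, values)):
            stack[r, m.ravel()[flat]] = v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if scheme == "median":
                vals = np.nanmedian(stack, axis=0)
            elif scheme == "min":
                vals = np.nanmin(stack, axis=0)
            elif scheme == "max":
                vals = np.nanmax(stack, axis=0)
            elif scheme == "trimmed_mean":
                vals = _trimmed_mean(stack, 0.2)
        agg = np.zeros(space.shape, dtype=float)
        agg.ravel()[flat] = np.nan_to_num(vals)
    agg[coverage == 0] = 0.0
    return PsaMap(parameter, grid.like(agg), cov_vol, n, scheme, sum_values)


def _trimmed_mean(stack: np.ndarray, fraction: float) -> np.ndarray:
    """Per-column mean after trimming ``fraction`` from each tail (NaN-aware)."""
    out = np.empty(stack.shape[1])
    for j in range(stack.shape[1]):
        col = np.sort(stack[:, j][~np.isnan(stack[:, j])])
        k = int(np.floor(fraction * col.size))
        trimmed = col[k: col.size - k] if col.size - 2 * k > 0 else col
        out[j] = trimmed.mean()
    return out


def update_psa(
    psa: PsaMap,
    case: CaseRecord,
    space: nspace.NormalizedSpace | None = None,
    method: str = "landmarks-given",
    **kwargs,
) -> PsaMap:
    """Incrementally fold one case into a mean-scheme PSA.

    Only the averaging schemes admit incremental extension; the others
    require a full rebuild from all cases.
    """
    if psa.scheme not in ("mean_global_n", "mean_coverage"):
        raise ValueError(f"scheme {psa.scheme!r} requires a full rebuild")
    if psa.sum_values is None:
        raise ValueError("PSA lacks retained sums; rebuild once with build_psa")
    if psa.parameter not in case.variables:
        raise ValueError(f"case {case.case_id} is missing parameter {psa.parameter!r}")
    space = space or default_psa_space()
    m = _normalized_masks([case], space, method, **kwargs)[0]
    v = float(case.variables[psa.parameter])
    s = psa.sum_values + m * v
    cov = psa.coverage.data + m
    n = psa.n_cases + 1
    if psa.scheme == "mean_global_n":
        agg = s / n
    else:
        agg = np.divide(s, cov, out=np.zeros_like(s), where=cov > 0)
    agg[cov == 0] = 0.0
    return PsaMap(
        psa.parameter, psa.aggregate.like(agg),
        psa.coverage.like(cov.astype(np.int32)), n, psa.scheme, s,
    )


def constrain_cases(
    cases: list[CaseRecord],
    target_case: CaseRecord,
    constraints: list,
) -> list[CaseRecord]:
    """Select the cases comparable to the target under the given constraints.

    Each constraint is ``(variable, n_ranges)`` - the variable's values over
    the cohort (excluding the target) are split into ``n_ranges`` quantile
    ranges (half-open, top range closed) and only cases in the range
    containing the target's value are kept - or ``(variable, (lo, hi))`` for
    an explicit half-open interval.  The target case is never returned
    (leave-one-out rule).
    """
    pool = [c for c in cases if c is not target_case and c.case_id != target_case.case_id]
    for variable, spec in constraints:
        for c in pool + [target_case]:
            if variable not in c.variables:
                raise ValueError(f"case {c.case_id} is missing variable {variable!r}")
        tv = float(target_case.variables[variable])
        if isinstance(spec, int):
            vals = np.array([float(c.variables[variable]) for c in pool])
            edges = np.quantile(vals, np.linspace(0, 1, spec + 1))
            bin_idx = int(np.clip(np.searchsorted(edges, tv, side="right") - 1, 0, spec - 1))
            lo, hi = edges[bin_idx], edges[bin_idx + 1]
            closed_top = bin_idx == spec - 1
        else:
            lo, hi = spec
            closed_top = False
        def inside(v: float) -> bool:
            return (lo <= v <= hi) if closed_top else (lo <= v < hi)
        pool = [c for c in pool if inside(float(c.variables[variable]))]
    if not pool:
        raise ValueError("no comparable cases satisfy the constraints")
    return pool


def predict(psa: PsaMap, lesion_mask_in_psa_space: Volume3D) -> PredictionResult:
    """Read the PSA statistics inside a normalized lesion ROI."""
    if lesion_mask_in_psa_space.shape != psa.aggregate.shape:
        raise ValueError("lesion mask grid must match the PSA grid")
    roi = (lesion_mask_in_psa_space.data > 0) & (psa.coverage.data > 0)
    if not roi.any():
        raise ValueError("ROI has no covered voxels in the PSA")
    vals = psa.aggregate.data[roi]
    p25, p50, p75 = np.percentile(vals, [25, 50, 75])
    return PredictionResult(
        parameter=psa.parameter,
        mean=float(vals.mean()), sd=float(vals.std()),
        p25=float(p25), p50=float(p50), p75=float(p75),
        n_voxels=int(roi.sum()),
    )


def loo_evaluate(
    cases: list[CaseRecord],
    outcome_params: list[str],
    scheme: str = "mean_coverage",
    constraints: list = (),
    space: nspace.NormalizedSpace | None = None,
    method: str = "landmarks-given",
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-out evaluation: predict each case from the remaining ones.

    Returns the per-case absolute-error table and the mean absolute error
    per parameter (plus ``overall``).  Per-case failures are recorded as
    NaN rather than aborting the evaluation.
    """
    if len(cases) < 3:
        raise ValueError("need at least 3 cases for leave-one-out evaluation")
    space = space or default_psa_space()
    rows = []
    for target in cases:
        row: dict = {"case_id": target.case_id}
        try:
            pool = constrain_cases(cases, target, list(constraints))
            roi = normalize_case(target, space, method, **kwargs)
            for param in outcome_params:
                psa = build_psa(pool, param, scheme, space, method, **kwargs)
                pred = predict(psa, roi)
                actual = float(target.variables[param])
                row[f"{param}_pred"] = pred.mean
                row[f"{param}_actual"] = actual
                row[f"{param}_abs_err"] = abs(pred.mean - actual)
        except ValueError as e:
            row["error"] = str(e)
            for param in outcome_params:
                row.setdefault(f"{param}_abs_err", np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    mae = {}
    for param in outcome_params:
        mae[param] = float(np.nanmean(table[f"{param}_abs_err"]))
    mae["overall"] = float(np.nanmean([mae[p] for p in outcome_params]))
    return table, mae


def enumerate_design(design: PsaDesign) -> dict[str, int]:
    """Instance counts of a multi-scheme, multi-constraint evaluation design.

    ``instances_per_case`` multiplies the aggregation schemes by the
    selection-range counts; the totals scale by the outcome parameters, the
    cohort size, and (for case processings) the leave-one-out pool size.
    """
    per_case = design.n_aggregations * int(np.prod(design.selection_range_counts))
    total = per_case * max(len(design.outcome_parameters), 1) * design.n_cases
    return {
        "instances_per_case": int(per_case),
        "total_instances": int(total),
        "total_case_processings": int(total * (design.n_cases - 1)),
    }
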