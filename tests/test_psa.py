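"""Probabilistic stroke atlas: aggregation, constraints, prediction, LOO."""

import numpy as np
import pytest

import strokeatlas as sa
from strokeatlas import space as nspace
from strokeatlas.atlas import make_space
from strokeatlas.lesionseg import contours_from_mask
from strokeatlas.mapping import LandmarkSet, build_transform
from strokeatlas.psa import (
    CaseRecord, PSA_SCHEMES, PsaDesign, build_psa, constrain_cases,
    default_psa_space, enumerate_design, loo_evaluate, normalize_case, predict,
    update_psa,
)
from strokeatlas.volume import Volume3D
from tests.conftest import dice

SPACE = default_psa_space()


# --- toy cohort directly on a coarse normalized grid -----------------------

TOY_SPACE = make_space(8.0)


def _toy_case(cid, mask, variables):
    """A case living directly on the toy PSA grid with an identity transform."""
    grid = Volume3D(mask.astype(np.uint8), TOY_SPACE.spacing, TOY_SPACE.origin)
    lms = LandmarkSet.from_space(TOY_SPACE.landmarks)
    case = CaseRecord(cid, grid, contours_from_mask(grid), variables)
    case.transform = build_transform(lms, lms)
    return case


def _toy_cohort(n=5, seed=0):
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        mask = np.zeros(TOY_SPACE.shape, dtype=bool)
        cx, cy, cz = rng.integers(3, np.asarray(TOY_SPACE.shape) - 4)
        w = rng.integers(2, 4, size=3)
        mask[cx - w[0]: cx + w[0], cy - w[1]: cy + w[1], cz - w[2]: cz + w[2]] = True
        cases.append(_toy_case(f"t{i}", mask, {"score": float(rng.integers(0, 7))}))
    return cases


def _brute_force_psa(cases, parameter, scheme, space):
    """Independent per-voxel loop over cases implementing each scheme."""
    masks = [normalize_case(c, space).data.astype(bool) for c in cases]
    values = [float(c.variables[parameter]) for c in cases]
    vols = [m.sum() for m in masks]
    agg = np.zeros(space.shape)
    cov = np.zeros(space.shape, dtype=int)
    for idx in np.ndindex(space.shape):
        vals = [v for m, v in zip(masks, values) if m[idx]]
        ws = [vol for m, vol in zip(masks, vols) if m[idx]]
        cov[idx] = len(vals)
        if not vals:
            continue
        if scheme == "mean_global_n":
            agg[idx] = sum(vals) / len(cases)
        elif scheme == "mean_coverage":
            agg[idx] = np.mean(vals)
        elif scheme == "median":
            agg[idx] = np.median(vals)
        elif scheme == "min":
            agg[idx] = min(vals)
        elif scheme == "max":
            agg[idx] = max(vals)
        elif scheme == "trimmed_mean":
            v = np.sort(vals)
            k = int(np.floor(0.2 * len(v)))
            v = v[k: len(v) - k] if len(v) - 2 * k > 0 else v
            agg[idx] = v.mean()
        elif scheme == "volume_weighted_mean":
            agg[idx] = np.average(vals, weights=ws)
        elif scheme == "inverse_volume_weighted_mean":
            agg[idx] = np.average(vals, weights=[1.0 / w for w in ws])
    return agg, cov


@pytest.mark.parametrize("scheme", PSA_SCHEMES)
def test_every_scheme_matches_brute_force_oracle(scheme):
    cases = _toy_cohort()
    psa = build_psa(cases, "score", scheme, TOY_SPACE)
    agg, cov = _brute_force_psa(cases, "score", scheme, TOY_SPACE)
    assert np.array_equal(psa.coverage.data, cov)
    assert np.allclose(psa.aggregate.data, agg)


def test_single_case_psa_is_indicator_times_value():
    (case,) = _toy_cohort(n=1, seed=3)
    case.variables["score"] = 3.0
    for scheme in ("mean_global_n", "mean_coverage"):
        psa = build_psa([case], "score", scheme, TOY_SPACE)
        roi = normalize_case(case, TOY_SPACE).data > 0
        assert np.allclose(psa.aggregate.data[roi], 3.0)
        assert np.allclose(psa.aggregate.data[~roi], 0.0)


def test_two_overlapping_cases_divisor_semantics():
    m1 = np.zeros(TOY_SPACE.shape, dtype=bool)
    m2 = np.zeros(TOY_SPACE.shape, dtype=bool)
    m1[4:8, 6:10, 5:9] = True
    m2[6:10, 6:10, 5:9] = True
    c1 = _toy_case("a", m1, {"score": 2.0})
    c2 = _toy_case("b", m2, {"score": 4.0})
    cov = build_psa([c1, c2], "score", "mean_coverage", TOY_SPACE).aggregate.data
    glob = build_psa([c1, c2], "score", "mean_global_n", TOY_SPACE).aggregate.data
    overlap = m1 & m2
    only1 = m1 & ~m2
    only2 = m2 & ~m1
    assert np.allclose(cov[overlap], 3.0) and np.allclose(glob[overlap], 3.0)
    assert np.allclose(cov[only1], 2.0) and np.allclose(glob[only1], 1.0)
    assert np.allclose(cov[only2], 4.0) and np.allclose(glob[only2], 2.0)


def test_coverage_conservation():
    cases = _toy_cohort(n=6, seed=9)
    psa = build_psa(cases, "score", "mean_coverage", TOY_SPACE)
    total = sum(normalize_case(c, TOY_SPACE).data.sum() for c in cases)
    assert psa.coverage.data.sum() == total


def test_unknown_scheme_and_missing_parameter_rejected():
    cases = _toy_cohort(n=2)
    with pytest.raises(ValueError, match="scheme"):
        build_psa(cases, "score", "fancy", TOY_SPACE)
    with pytest.raises(ValueError, match="t0"):
        build_psa(cases, "not_a_variable", "mean_coverage", TOY_SPACE)


def test_incremental_update_equals_rebuild():
    cases = _toy_cohort(n=6, seed=4)
    for scheme in ("mean_coverage", "mean_global_n"):
        partial = build_psa(cases[:5], "score", scheme, TOY_SPACE)
        inc = update_psa(partial, cases[5], TOY_SPACE)
        full = build_psa(cases, "score", scheme, TOY_SPACE)
        assert np.allclose(inc.aggregate.data, full.aggregate.data)
        assert np.array_equal(inc.coverage.data, full.coverage.data)
    with pytest.raises(ValueError, match="rebuild"):
        update_psa(build_psa(cases, "score", "median", TOY_SPACE), cases[0], TOY_SPACE)


# --- normalization ---------------------------------------------------------

def test_identity_regime_normalization(small_cohort):
    """A case generated in atlas pose normalizes onto its own analytic lesion."""
    case = small_cohort[0]
    roi = normalize_case(case, SPACE)
    spec = case.meta["lesion_spec"]
    xs, ys, zs = SPACE.world_coords()
    truth = nspace.ellipsoid_mask(xs, ys, zs, np.asarray(spec.center_mm),
                                  np.full(3, spec.radius_mm))
    assert dice(roi.data, truth) >= 0.9
    vol_roi = roi.data.sum() * np.prod(SPACE.spacing) / 1000.0
    assert vol_roi == pytest.approx(case.variables["infarct_volume_ml"], rel=0.1)


def test_normalization_undoes_known_anisotropic_scale(small_cohort):
    """Stretching a case 1.2x anteriorly: the normalized ROI recovers the
    canonical lesion volume within 10%."""
    base = small_cohort[1]
    v = base.scan
    stretched_scan = Volume3D(v.data, (v.spacing[0], v.spacing[1] * 1.2, v.spacing[2]),
                              (v.origin[0], v.origin[1] * 1.2, v.origin[2]))
    lm = base.truth_landmarks
    stretched_lms = LandmarkSet(
        AC=lm.AC * [1, 1.2, 1], PC=lm.PC * [1, 1.2, 1], L=lm.L, R=lm.R,
        A=lm.A * 1.2, P=lm.P * 1.2, S=lm.S, I=lm.I,
        CC_top=lm.CC_top, OF_ventral=lm.OF_ventral)
    cs = base.lesion_contours
    stretched_contours = type(cs)(
        {k: [p * np.array([1.0, 1.2]) for p in polys] for k, polys in cs.slices.items()},
        cs.grid_shape, stretched_scan.spacing, stretched_scan.origin)
    case = CaseRecord("stretched", stretched_scan, stretched_contours, {},
                      truth_landmarks=stretched_lms, truth_frame=np.eye(3),
                      truth_frame_origin=np.zeros(3))
    roi = normalize_case(case, SPACE)
    vol_norm = roi.data.sum() * np.prod(SPACE.spacing) / 1000.0
    assert vol_norm == pytest.approx(base.variables["infarct_volume_ml"], rel=0.1)


def test_empty_contours_rejected():
    from strokeatlas.lesionseg import ContourSet
    grid = Volume3D(np.zeros((8, 8, 8), np.uint8), (2, 2, 2))
    with pytest.raises(ValueError, match="empty"):
        CaseRecord("x", grid, ContourSet.empty_like(grid), {})


# --- constraints -----------------------------------------------------------

def test_no_constraints_returns_all_but_target(small_cohort):
    subset = constrain_cases(small_cohort, small_cohort[3], [])
    assert len(subset) == len(small_cohort) - 1
    assert small_cohort[3] not in subset


def test_quartile_constraint_selects_matching_range(small_cohort):
    target = small_cohort[0]
    subset = constrain_cases(small_cohort, target, [("infarct_volume_ml", 4)])
    pool = [c for c in small_cohort if c is not target]
    vals = np.array([c.variables["infarct_volume_ml"] for c in pool])
    edges = np.quantile(vals, [0, 0.25, 0.5, 0.75, 1.0])
    tv = target.variables["infarct_volume_ml"]
    b = int(np.clip(np.searchsorted(edges, tv, side="right") - 1, 0, 3))
    for c in subset:
        v = c.variables["infarct_volume_ml"]
        if b == 3:
            assert edges[3] <= v <= edges[4]
        else:
            assert edges[b] <= v < edges[b + 1]
    assert target not in subset


def test_target_excluded_even_when_it_satisfies_constraints(small_cohort):
    target = small_cohort[2]
    tv = target.variables["infarct_volume_ml"]
    subset = constrain_cases(small_cohort, target,
                             [("infarct_volume_ml", (tv - 1, tv + 1))])
    assert target not in subset


def test_unsatisfiable_constraint_raises(small_cohort):
    with pytest.raises(ValueError, match="no comparable cases"):
        constrain_cases(small_cohort, small_cohort[0],
                        [("infarct_volume_ml", (1e6, 1e7))])


# --- prediction ------------------------------------------------------------

def test_prediction_on_constant_psa():
    cases = _toy_cohort(n=4, seed=6)
    for c in cases:
        c.variables["score"] = 5.0
    psa = build_psa(cases, "score", "mean_coverage", TOY_SPACE)
    roi = normalize_case(cases[0], TOY_SPACE)
    pred = predict(psa, roi)
    assert pred.mean == pred.p50 == pytest.approx(5.0)
    assert pred.sd == pytest.approx(0.0)


def test_prediction_mean_over_two_equal_zones():
    m1 = np.zeros(TOY_SPACE.shape, dtype=bool)
    m2 = np.zeros(TOY_SPACE.shape, dtype=bool)
    m1[2:6, 4:8, 4:8] = True
    m2[8:12, 4:8, 4:8] = True
    c1 = _toy_case("a", m1, {"score": 2.0})
    c2 = _toy_case("b", m2, {"score": 4.0})
    psa = build_psa([c1, c2], "score", "mean_coverage", TOY_SPACE)
    roi = Volume3D((m1 | m2).astype(np.uint8), TOY_SPACE.spacing, TOY_SPACE.origin)
    pred = predict(psa, roi)
    assert pred.mean == pytest.approx(3.0)


def test_prediction_percentiles_match_sort_oracle():
    cases = _toy_cohort(n=7, seed=12)
    psa = build_psa(cases, "score", "mean_coverage", TOY_SPACE)
    roi = normalize_case(cases[2], TOY_SPACE)
    pred = predict(psa, roi)
    sel = (roi.data > 0) & (psa.coverage.data > 0)
    vals = np.sort(psa.aggregate.data[sel])
    assert pred.p25 == pytest.approx(np.percentile(vals, 25))
    assert pred.p50 == pytest.approx(np.percentile(vals, 50))
    assert pred.p75 == pytest.approx(np.percentile(vals, 75))
    assert pred.n_voxels == sel.sum()


def test_prediction_without_coverage_rejected():
    cases = _toy_cohort(n=2, seed=1)
    psa = build_psa(cases[:1], "score", "mean_coverage", TOY_SPACE)
    empty_roi = Volume3D(np.zeros(TOY_SPACE.shape, np.uint8),
                         TOY_SPACE.spacing, TOY_SPACE.origin)
    with pytest.raises(ValueError, match="covered"):
        predict(psa, empty_roi)


# --- leave-one-out evaluation ----------------------------------------------

def test_loo_on_constant_outcome_is_exact():
    cases = _toy_cohort(n=5, seed=8)
    for c in cases:
        c.variables["score"] = 3.0
    _, mae = loo_evaluate(cases, ["score"], scheme="mean_coverage", space=TOY_SPACE)
    assert mae["score"] == pytest.approx(0.0, abs=1e-12)


NOISELESS = {
    "mRS_day90": sa.OutcomeModel("linear", 3.0, (0.0, -1.0 / 40.0, 0.0), noise_sd=0.0),
}


def test_loo_recovers_location_coupled_outcome():
    cohort = sa.make_cohort(sa.CohortSpec(
        n_cases=60, seed=5, outcome_names=("mRS_day90",), coupling=NOISELESS))
    _, mae = loo_evaluate(cohort, ["mRS_day90"], scheme="mean_coverage", space=SPACE)
    assert mae["mRS_day90"] <= 0.5


def test_loo_error_shrinks_with_cohort_size():
    c20 = sa.make_cohort(sa.CohortSpec(
        n_cases=20, seed=5, outcome_names=("mRS_day90",), coupling=NOISELESS))
    c100 = sa.make_cohort(sa.CohortSpec(
        n_cases=100, seed=5, outcome_names=("mRS_day90",), coupling=NOISELESS))
    _, m20 = loo_evaluate(c20, ["mRS_day90"], space=SPACE)
    _, m100 = loo_evaluate(c100, ["mRS_day90"], space=SPACE)
    assert m100["mRS_day90"] < m20["mRS_day90"]


def test_volume_constraint_does_not_worsen_prediction():
    cohort = sa.make_cohort(sa.CohortSpec(n_cases=40, seed=3))
    _, plain = loo_evaluate(cohort, ["mRS_day90"], space=SPACE)
    _, constrained = loo_evaluate(cohort, ["mRS_day90"],
                                  constraints=[("infarct_volume_ml", 4)], space=SPACE)
    assert constrained["mRS_day90"] <= plain["mRS_day90"]


def test_loo_needs_three_cases():
    cases = _toy_cohort(n=2)
    with pytest.raises(ValueError, match="3 cases"):
        loo_evaluate(cases, ["score"], space=TOY_SPACE)


# --- design enumeration ----------------------------------------------------

def test_design_enumeration_counts():
    design = PsaDesign(n_aggregations=8, selection_range_counts=(4, 4, 4),
                       outcome_parameters=tuple(f"p{i}" for i in range(9)),
                       n_cases=128)
    counts = enumerate_design(design)
    assert counts["instances_per_case"] == 512
    assert counts["total_instances"] == 589_824
    assert counts["total_case_processings"] == 74_907_648
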