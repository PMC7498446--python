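"""Ellipse landmarks and the piecewise-linear atlas transform."""

import numpy as np
import pytest

import strokeatlas as sa
from strokeatlas import space
from strokeatlas.mapping import (
    LandmarkSet, MipImage, apply_to_labels, build_transform, cortex_outline,
    fit_ellipse, frame_from_fit, landmarks_from_ellipse, mip_slab,
)
from tests.conftest import dice, warp_with_truth


def atlas_landmarks():
    return LandmarkSet.from_space(space.default_landmarks())


# --- MIP slab --------------------------------------------------------------

def test_mip_single_voxel_width_equals_resampled_slice(symmetric_phantom):
    plane = symmetric_phantom.truth_msp
    thin = mip_slab(symmetric_phantom.volume, plane, width_mm=1.0)
    # independent resample of the central plane
    pts = (thin.plane_origin[None, None, :]
           + thin.us[:, None, None] * thin.u_dir[None, None, :]
           + thin.vs[None, :, None] * thin.v_dir[None, None, :])
    direct = symmetric_phantom.volume.sample_world(pts.reshape(-1, 3)).reshape(thin.image.shape)
    assert np.allclose(thin.image, direct)


def test_mip_dominates_central_slice(symmetric_phantom):
    plane = symmetric_phantom.truth_msp
    thin = mip_slab(symmetric_phantom.volume, plane, width_mm=1.0)
    wide = mip_slab(symmetric_phantom.volume, plane, width_mm=12.0)
    assert (wide.image >= thin.image - 1e-9).all()


def test_mip_captures_bright_off_midline_dot():
    ph = sa.make_head_phantom(sa.PhantomConfig(noise_sd=0.0, seed=0))
    data = ph.volume.data.copy()
    i = ph.volume.world_to_index([-3.0, 0.0, 0.0]).round().astype(int)
    data[i[0], i[1], i[2]] = 240.0
    vol = ph.volume.like(data)
    wide = mip_slab(vol, ph.truth_msp, width_mm=10.0)
    assert wide.image.max() >= 239.0


def test_mip_slab_outside_volume_rejected(symmetric_phantom):
    from strokeatlas.volume import Plane
    far = Plane(np.array([1.0, 0, 0]), 4000.0)
    with pytest.raises(ValueError, match="outside"):
        mip_slab(symmetric_phantom.volume, far, width_mm=5.0)


# --- cortex outline --------------------------------------------------------

def _disk_mip(radius=30.0, value=100.0, n=101, sp=1.0):
    half = (n - 1) / 2 * sp
    us = np.linspace(-half, half, n)
    uu, vv = np.meshgrid(us, us, indexing="ij")
    img = np.where(uu**2 + vv**2 <= radius**2, value, 0.0)
    return MipImage(img, us, us, np.zeros(3),
                    np.array([0.0, 1, 0]), np.array([0.0, 0, 1]), np.array([1.0, 0, 0]))


def test_outline_of_binary_disk_lies_on_circle():
    mip = _disk_mip(radius=30.0)
    pts = cortex_outline(mip, lower_threshold=50.0, upper_threshold=200.0)
    r = np.linalg.norm(pts, axis=1)
    assert np.all(np.abs(r - 30.0) <= 1.0)
    assert len(pts) >= 64


def test_outline_of_empty_image_rejected():
    mip = _disk_mip(value=10.0)
    with pytest.raises(ValueError, match="cortex"):
        cortex_outline(mip, lower_threshold=50.0, upper_threshold=200.0)


def test_phantom_outline_tracks_true_midsagittal_ellipse(symmetric_phantom):
    plane = sa.extract_msp(symmetric_phantom.volume)
    mip = mip_slab(symmetric_phantom.volume, plane, 10.0)
    pts = cortex_outline(mip, 70.0, 200.0)
    # true cross-section: ellipse a=85 (y), b=57 (z); the MIP plane origin is
    # the projected volume center, i.e. the brain center, so the plane
    # coordinates are already ellipse-centered
    q = (pts[:, 0] / space.BRAIN_SEMIAXES[1])**2 + \
        (pts[:, 1] / space.BRAIN_SEMIAXES[2])**2
    # radial deviation in mm, approximated via the implicit value
    assert np.percentile(np.abs(np.sqrt(q) - 1.0), 95) * space.BRAIN_SEMIAXES[2] <= 2.0


# --- ellipse fitting -------------------------------------------------------

def _ellipse_samples(a, b, center=(0.0, 0.0), theta=0.0, n=64, rng=None, jitter=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts = pts @ rot.T + np.asarray(center)
    if jitter:
        pts = pts + rng.normal(0, jitter, pts.shape)
    return pts


def test_fit_recovers_exact_ellipse():
    fit = fit_ellipse(_ellipse_samples(86.0, 58.0, center=(3.0, -2.0), theta=0.1))
    assert fit.a == pytest.approx(86.0, abs=0.1)
    assert fit.b == pytest.approx(58.0, abs=0.1)
    assert np.allclose(fit.center, [3.0, -2.0], atol=0.1)


def test_fit_circle_gives_equal_axes():
    fit = fit_ellipse(_ellipse_samples(40.0, 40.0))
    assert fit.a == pytest.approx(fit.b, abs=1e-6)


def test_fit_with_1mm_jitter_within_1mm():
    rng = np.random.default_rng(5)
    fit = fit_ellipse(_ellipse_samples(86.0, 58.0, n=128, rng=rng, jitter=1.0))
    assert fit.a == pytest.approx(86.0, abs=1.0)
    assert fit.b == pytest.approx(58.0, abs=1.0)


def test_fit_rejects_degenerate_input():
    line = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 5, 20)])
    with pytest.raises(ValueError):
        fit_ellipse(line)
    with pytest.raises(ValueError):
        fit_ellipse(line[:4])


# --- landmarks from the ellipse --------------------------------------------

def test_atlas_space_ellipse_reproduces_stored_landmarks():
    """Calibration oracle: the normalized-space cortex ellipse must map back
    onto the space's own stored AC and PC within 0.5 mm."""
    a, b = space.BRAIN_SEMIAXES[1], space.BRAIN_SEMIAXES[2]
    center = np.array([space.BRAIN_CENTER[1], space.BRAIN_CENTER[2]])
    fit = fit_ellipse(_ellipse_samples(a, b, center=tuple(center)))
    lms = landmarks_from_ellipse(fit)
    ac_world = np.array([0.0, center[0] + lms.AC[1], center[1] + lms.AC[2]])
    pc_world = np.array([0.0, center[0] + lms.PC[1], center[1] + lms.PC[2]])
    assert np.linalg.norm(ac_world - space.AC) <= 0.5
    assert np.linalg.norm(pc_world - space.PC) <= 0.5
    assert lms.CC_top + center[1] == pytest.approx(space.CC_TOP, abs=0.5)
    assert lms.OF_ventral + center[1] == pytest.approx(space.OF_VENTRAL, abs=0.5)


def test_landmarks_scale_homogeneously_with_the_fit():
    from strokeatlas.mapping import EllipseFit
    base = EllipseFit(np.zeros(2), 80.0, 50.0, 0.0)
    doubled = EllipseFit(np.zeros(2), 160.0, 100.0, 0.0)
    l1 = landmarks_from_ellipse(base)
    l2 = landmarks_from_ellipse(doubled)
    assert np.allclose(l2.AC, 2 * l1.AC)
    assert l2.A == pytest.approx(2 * l1.A)
    assert l2.S == pytest.approx(2 * l1.S)
    assert l2.L == pytest.approx(2 * l1.L)


def test_anterior_posterior_landmarks_at_major_axis_extremes():
    from strokeatlas.mapping import EllipseFit
    fit = EllipseFit(np.array([5.0, 1.0]), 80.0, 50.0, 0.0)
    lms = landmarks_from_ellipse(fit)
    assert lms.A == pytest.approx(80.0)
    assert lms.P == pytest.approx(-80.0)


# --- piecewise-linear transform --------------------------------------------

def test_region_and_dof_counts():
    src = atlas_landmarks()
    t12 = build_transform(src, src, extended=False)
    t24 = build_transform(src, src, extended=True)
    assert t12.n_regions == 12 and t12.dof == 13
    assert t24.n_regions == 24 and t24.dof == 15


def test_identity_transform_on_test_points():
    src = atlas_landmarks()
    t = build_transform(src, src)
    rng = np.random.default_rng(0)
    pts = rng.uniform([-60, -90, -35], [60, 60, 65], size=(200, 3))
    assert np.allclose(t.apply(pts, warn=False), pts, atol=1e-12)


def test_landmark_ordering_violation_rejected():
    with pytest.raises(ValueError, match="ordering"):
        LandmarkSet(AC=[0, 0, 0], PC=[0, 10, 0], L=-60, R=60, A=70, P=-100, S=70, I=-40)
    with pytest.raises(ValueError, match="ordering"):
        LandmarkSet(AC=[0, 0, 0], PC=[0, -24, 0], L=60, R=-60, A=70, P=-100, S=70, I=-40)


def test_extended_transform_requires_extended_landmarks():
    src = atlas_landmarks()
    bare = LandmarkSet(AC=src.AC, PC=src.PC, L=src.L, R=src.R, A=src.A, P=src.P,
                       S=src.S, I=src.I)
    with pytest.raises(ValueError, match="extended"):
        build_transform(src, bare, extended=True)


def test_ac_maps_exactly_to_target_ac():
    src = atlas_landmarks()
    tgt = LandmarkSet(AC=[0.0, 3.0, -2.0], PC=[0.0, -20.0, -2.0], L=-70, R=72,
                      A=75, P=-110, S=80, I=-45, CC_top=30.0, OF_ventral=-16.0)
    t = build_transform(src, tgt, extended=True)
    assert np.allclose(t.apply(src.AC.reshape(1, 3)), tgt.AC, atol=1e-12)
    assert np.allclose(t.apply(src.PC.reshape(1, 3)), tgt.PC, atol=1e-12)


def test_apply_inverse_round_trip_exact():
    src = atlas_landmarks()
    tgt = LandmarkSet(AC=[0.0, 3.0, -2.0], PC=[0.0, -20.0, -2.0], L=-70, R=72,
                      A=75, P=-110, S=80, I=-45)
    rot = sa.rotation_matrix(9.0, 3.0, -4.0)
    t = build_transform(src, tgt, frame_rot=rot, frame_origin=np.array([1.0, -2, 3]))
    rng = np.random.default_rng(1)
    pts = rng.uniform([-60, -95, -38], [60, 62, 68], size=(1000, 3))
    back = t.inverse_apply(t.apply(pts, warn=False))
    assert np.max(np.linalg.norm(back - pts, axis=1)) < 1e-6


def test_adjacent_region_formulas_agree_on_shared_plane():
    src = atlas_landmarks()
    tgt = LandmarkSet(AC=[0.0, 2.0, 1.0], PC=[0.0, -25.0, 1.0], L=-60, R=64,
                      A=72, P=-95, S=68, I=-40)
    t = build_transform(src, tgt)
    regions = t.regions
    # find two regions sharing the AC-PC coronal face and evaluate a point on it
    probe = np.array([-30.0, src.AC[1], 20.0])  # on the y = AC_y plane
    images = []
    for r in regions:
        on_face = (r.src_lo <= probe).all() and (probe <= r.src_hi).all()
        if on_face:
            images.append(r.apply(probe)[0])
    assert len(images) >= 2
    for img in images[1:]:
        assert np.allclose(img, images[0], atol=1e-9)


def test_points_outside_bounding_box_clamped_with_warning():
    src = atlas_landmarks()
    t = build_transform(src, src)
    with pytest.warns(UserWarning, match="clamped"):
        out = t.apply(np.array([[500.0, 0.0, 0.0]]))
    assert out[0, 0] == pytest.approx(src.R)


# --- individualization -----------------------------------------------------

def test_identity_regime_individualization(bundle, symmetric_phantom):
    """A phantom generated in atlas pose with exact landmarks gets labels
    identical (>= 99%) to a direct resample of the atlas."""
    warped, t = warp_with_truth(bundle, symmetric_phantom)
    ident = build_transform(atlas_landmarks(), atlas_landmarks())
    direct = apply_to_labels(ident, bundle.territories, symmetric_phantom.volume)
    m = (direct.data > 0) | (warped.territories.data > 0)
    assert (warped.territories.data[m] == direct.data[m]).mean() >= 0.99


def test_labeled_volume_matches_brain_volume(bundle, symmetric_phantom):
    warped, _ = warp_with_truth(bundle, symmetric_phantom)
    labeled = (warped.territories.data > 0).sum()
    brain = (symmetric_phantom.brain_mask.data > 0).sum()
    assert abs(labeled - brain) / brain < 0.02


def test_ellipse_chain_runs_on_thick_slices_without_commissures(bundle):
    # the statistical path requires no AC/PC-visible voxels at all
    ph = sa.make_head_phantom(sa.PhantomConfig(slice_thickness_mm=6.0, seed=21))
    warped, t = sa.individualize_atlas(bundle, ph.volume,
                                       outline_thresholds=(70.0, 200.0))
    a_est = t.target_landmarks.A - t.target_landmarks.AC[1]
    assert a_est == pytest.approx(space.CORTEX_A, abs=8.0)
    assert (warped.territories.data > 0).any()


def test_anisotropic_scan_stretches_anterior_parcels(bundle, symmetric_phantom):
    """A scan stretched 1.2x antero-posteriorly yields a transform whose
    anterior scale factor is 1.2x the identity, within 5%."""
    v = symmetric_phantom.volume
    stretched = sa.Volume3D(v.data, (v.spacing[0], v.spacing[1] * 1.2, v.spacing[2]),
                            (v.origin[0], v.origin[1] * 1.2, v.origin[2]))
    warped, t = sa.individualize_atlas(bundle, stretched,
                                       outline_thresholds=(70.0, 200.0))
    span_scan = t.target_landmarks.A - t.target_landmarks.P
    span_atlas = space.CORTEX_A - space.CORTEX_P
    assert span_scan / span_atlas == pytest.approx(1.2, rel=0.05)


def test_rotated_scan_keeps_mirror_consistent_territories(bundle):
    """Territory masks individualized onto a 20-degree-yaw scan stay mirror
    consistent about the extracted MSP (Jaccard >= 0.9)."""
    ph = sa.make_head_phantom(sa.PhantomConfig(rotation_deg=(20, 0, 0), seed=22))
    warped, t = sa.individualize_atlas(bundle, ph.volume,
                                       outline_thresholds=(70.0, 200.0))
    assert sa.angular_error_deg(t.frame_rot[:, 0], ph.truth_msp.normal) <= 2.0
    # resample the labels onto a grid aligned with the extracted midplane so
    # that mirroring is an exact index flip
    sp = 1.5
    xf = (np.arange(96) - 47.5) * sp
    yf = (np.arange(128) - 63.5) * sp
    zf = (np.arange(96) - 47.5) * sp
    ff = np.stack(np.meshgrid(xf, yf, zf, indexing="ij"), axis=-1).reshape(-1, 3)
    world = t.frame_origin + ff @ t.frame_rot.T
    vol = warped.territories
    idx = np.rint(vol.world_to_index(world)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
    lab = np.zeros(len(world), dtype=vol.data.dtype)
    lab[ok] = vol.data[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    lab = lab.reshape(96, 128, 96)
    codes = {info.name: c for c, info in bundle.legend.items()}
    left = lab == codes["MCA_terminal_left"]
    right = lab == codes["MCA_terminal_right"]
    jacc = (left[::-1] & right).sum() / (left[::-1] | right).sum()
    assert jacc >= 0.9


def test_transform_serialization_round_trip():
    from strokeatlas.mapping import PiecewiseLinearTransform
    src = atlas_landmarks()
    tgt = LandmarkSet(AC=[0.0, 3.0, -2.0], PC=[0.0, -20.0, -2.0], L=-70, R=72,
                      A=75, P=-110, S=80, I=-45, CC_top=30.0, OF_ventral=-16.0)
    t = build_transform(src, tgt, extended=True,
                        frame_rot=sa.rotation_matrix(5, 0, 3),
                        frame_origin=np.array([1.0, 2.0, 3.0]))
    back = PiecewiseLinearTransform.from_dict(t.to_dict())
    pts = np.random.default_rng(2).uniform(-40, 40, (50, 3))
    assert np.allclose(back.apply(pts, warn=False), t.apply(pts, warn=False))
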