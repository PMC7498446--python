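"""Atlas-ROI analysis: left-right detection, quantification, thrombolysis.

Detection compares every lateralized atlas ROI with its mirror partner in 3D
(type-I regime): a pair is *mismatched* when the difference in mean, SD or
histogram peak height exceeds user-settable thresholds; within mismatched
pairs, voxels hypodense or hyperdense relative to the mirror ROI's
statistics provide infarct and hemorrhage evidence respectively.
Quantification (type-II regime) tallies the volume and percentage that each
atlas structure contributes to a scan-derived ROI.  The thrombolysis
assessment computes, fully in 3D, the infarct-to-territory ratios gated by
the classical one-third and one-half eligibility thresholds and the
diffusion-perfusion mismatch ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .atlas import AtlasBundle, LabelInfo
from .lesionseg import CONN26, extract_brain_ct, remove_csf
from .volume import Volume3D

HIST_EDGES_8BIT = np.linspace(0.0, 255.0, 65)


@dataclass
class RoiStats:
    code: int
    name: str
    side: str
    voxel_count: int
    mean: float           # 8-bit scale
    sd: float             # population convention
    peak_height: float    # max of the normalized 64-bin histogram
    histogram: np.ndarray


@dataclass
class DetectionThresholds:
    """User-settable normality/pathology discrimination thresholds (8-bit)."""

    t_mean: float = 6.0
    t_sd: float = 6.0
    t_peak: float = 0.05
    bin_ratio: float = 3.0        # over-representation ratio flagging a histogram bin
    min_bin_mass: float = 0.01    # smallest flagged-bin probability mass
    mean_margin: float = 5.0      # hypo/hyper split margin around the mirror mean
    min_finding_ml: float = 0.5   # smallest reportable evidence component
    min_roi_voxels: int = 100     # pairs smaller than this are too noisy to compare
    csf_floor: float = 50.0       # residual CSF below this 8-bit value is ignored


@dataclass
class Finding:
    kind: str                     # "infarct" | "hemorrhage"
    side: str
    slice_indices: list[int]
    anatomy_structures: list[str]
    territories: list[str]
    pair_means: dict[str, tuple[float, float]]  # label name -> (left, right)
    volume_ml: float


@dataclass
class DetectionReport:
    diagnosis: str
    findings: list[Finding]
    thresholds: DetectionThresholds

    def __post_init__(self) -> None:
        if (self.diagnosis == "not_detected") != (len(self.findings) == 0):
            raise ValueError("diagnosis inconsistent with findings")

    def to_dict(self) -> dict:
        return {
            "diagnosis": self.diagnosis,
            "thresholds": vars(self.thresholds),
            "findings": [
                {**vars(f), "pair_means": {k: list(v) for k, v in f.pair_means.items()}}
                for f in self.findings
            ],
        }

    def to_text(self) -> str:
        lines = [f"Diagnosis: {self.diagnosis}", ""]
        for i, f in enumerate(self.findings, 1):
            lines += [
                f"Finding {i}: {f.kind} ({f.side}), {f.volume_ml:.1f} ml",
                f"  slices: {', '.join(map(str, f.slice_indices))}",
                "  Blood supply territories:",
            ]
            for name in f.territories:
                lr = f.pair_means.get(name)
                suffix = f"  (R: {lr[1]:.1f}  L: {lr[0]:.1f})" if lr else ""
                lines.append(f"    {name}{suffix}")
            lines.append("  Anatomic structures:")
            for name in f.anatomy_structures:
                lr = f.pair_means.get(name)
                suffix = f"  (R: {lr[1]:.1f}  L: {lr[0]:.1f})" if lr else ""
                lines.append(f"    {name}{suffix}")
        return "\n".join(lines)


def _rescale_8bit(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if lo >= 0.0 and hi <= 255.0:
        return data
    if hi - lo < 1e-12:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo) * 255.0


def roi_stats(
    volume: Volume3D,
    labels: Volume3D,
    csf_removed_mask: Volume3D | None = None,
    legend: dict[int, LabelInfo] | None = None,
) -> list[RoiStats]:
    """Per-label 3D intensity statistics on the 8-bit scale."""
    if labels.shape != volume.shape:
        raise ValueError("labels must be individualized onto the scan grid")
    data = _rescale_8bit(volume.data)
    keep = np.ones(volume.shape, dtype=bool)
    if csf_removed_mask is not None:
        keep = csf_removed_mask.data > 0
    codes = np.unique(labels.data)
    codes = codes[codes > 0]
    if codes.size == 0:
        raise ValueError("label volume is empty")
    out = []
    for code in codes:
        mask = (labels.data == code) & keep
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"ROI {code} empty after masking; omitted")
            continue
        vals = data[mask]
        counts, _ = np.histogram(vals, bins=HIST_EDGES_8BIT)
        probs = counts / counts.sum()
        info = (legend or {}).get(int(code))
        out.append(RoiStats(
            code=int(code),
            name=info.name if info else str(code),
            side=info.laterality if info else "unknown",
            voxel_count=n,
            mean=float(vals.mean()),
            sd=float(vals.std()),  # population convention (ddof=0)
            peak_height=float(probs.max()),
            histogram=probs,
        ))
    if not out:
        raise ValueError("all ROIs empty")
    return out


def _pair_mismatch(a: RoiStats, b: RoiStats, thr: DetectionThresholds) -> bool:
    return (
        abs(a.mean - b.mean) > thr.t_mean
        or abs(a.sd - b.sd) > thr.t_sd
        or abs(a.peak_height - b.peak_height) > thr.t_peak
    )


def detect_stroke(
    volume: Volume3D,
    bundle: AtlasBundle,
    thresholds: DetectionThresholds | None = None,
    csf_removed_mask: Volume3D | None = None,
) -> DetectionReport:
    """Type-I ROI detection: mirror-pair comparison over both atlases.

    ``bundle`` must already be individualized onto the scan grid.  If no
    CSF-removed mask is given, one is computed by CT brain extraction plus
    template-confined CSF removal (falling back to the whole grid on
    non-CT volumes).
    """
    thr = thresholds or DetectionThresholds()
    if csf_removed_mask is None:
        try:
            brain = extract_brain_ct(volume)
            csf_removed_mask = remove_csf(volume, brain, bundle.ventricle_template)
        except ValueError:
            csf_removed_mask = None

    data = _rescale_8bit(volume.data)
    keep = csf_removed_mask.data > 0 if csf_removed_mask is not None else np.ones(volume.shape, bool)
    # residual CSF outside the ventricle template (e.g. the interhemispheric
    # fissure) overlaps infarct densities and is excluded outright
    keep = keep & (data >= thr.csf_floor)
    keep_vol = volume.like(keep.astype(np.uint8))

    hypo_evidence = np.zeros(volume.shape, dtype=bool)
    hyper_evidence = np.zeros(volume.shape, dtype=bool)
    pair_means: dict[str, tuple[float, float]] = {}

    for label_vol in (bundle.anatomy, bundle.territories):
        stats = {
            s.code: s
            for s in roi_stats(volume, label_vol, keep_vol, bundle.legend)
        }
        for code, s in stats.items():
            info = bundle.legend.get(code)
            if info is None or info.laterality != "left":
                continue
            if info.mirror_code not in bundle.legend:
                raise ValueError(f"label {code} ({info.name}) has no mirror code "
                                 "in the legend")
            m = stats.get(info.mirror_code)
            if m is None:
                continue
            if min(s.voxel_count, m.voxel_count) < thr.min_roi_voxels:
                continue
            base = info.name.removesuffix("_left")
            pair_means[base] = (s.mean, m.mean)
            if not _pair_mismatch(s, m, thr):
                continue
            # evidence: intensity bins over-represented relative to the
            # mirror ROI's density curve, split into hypo-/hyperdense by
            # their position against the mirror mean
            centers = 0.5 * (HIST_EDGES_8BIT[:-1] + HIST_EDGES_8BIT[1:])
            binned = np.clip(
                np.digitize(data, HIST_EDGES_8BIT) - 1, 0, len(centers) - 1
            )
            for s_this, s_other, lbl_code in ((s, m, code), (m, s, info.mirror_code)):
                eps = 1e-6
                ratio = (s_this.histogram + eps) / (s_other.histogram + eps)
                flagged = (ratio >= thr.bin_ratio) & (s_this.histogram >= thr.min_bin_mass)
                roi = (label_vol.data == lbl_code) & keep
                hypo_bins = flagged & (centers < s_other.mean - thr.mean_margin)
                hyper_bins = flagged & (centers > s_other.mean + thr.mean_margin)
                hypo_evidence |= roi & hypo_bins[binned]
                hyper_evidence |= roi & hyper_bins[binned]

    findings = []
    findings += _components_to_findings(hypo_evidence, "infarct", volume, bundle, thr, pair_means)
    findings += _components_to_findings(hyper_evidence, "hemorrhage", volume, bundle, thr, pair_means)

    kinds = {f.kind for f in findings}
    if not findings:
        diagnosis = "not_detected"
    elif kinds == {"infarct"}:
        diagnosis = "infarct"
    elif kinds == {"hemorrhage"}:
        diagnosis = "hemorrhage"
    else:
        inf_terr = set().union(*(f.territories for f in findings if f.kind == "infarct"))
        hem_terr = set().union(*(f.territories for f in findings if f.kind == "hemorrhage"))
        if inf_terr & hem_terr:
            diagnosis = "infarct_with_hemorrhagic_transformation"
        else:
            diagnosis = "hemorrhage"
    return DetectionReport(diagnosis, findings, thr)


def _components_to_findings(evidence, kind, volume, bundle, thr, pair_means):
    lab, n = ndimage.label(evidence, structure=CONN26)
    vox_ml = volume.voxel_volume_ml()
    out = []
    for c in range(1, n + 1):
        comp = lab == c
        vol_ml = float(comp.sum() * vox_ml)
        if vol_ml < thr.min_finding_ml:
            continue
        idx = np.argwhere(comp)
        slices = sorted(set(int(k) for k in idx[:, 2]))
        anat_codes = np.unique(bundle.anatomy.data[comp])
        terr_codes = np.unique(bundle.territories.data[comp])
        names = lambda codes: sorted(
            bundle.legend[int(cd)].name for cd in codes if int(cd) in bundle.legend
        )
        centroid_x = volume.index_to_world(idx.mean(axis=0))[0]
        side_votes = [
            bundle.legend[int(cd)].laterality for cd in terr_codes if int(cd) in bundle.legend
        ]
        side = max(set(side_votes), key=side_votes.count) if side_votes else (
            "left" if centroid_x < 0 else "right"
        )
        relevant = {
            bundle.legend[int(cd)].name.removesuffix("_left").removesuffix("_right")
            for cd in list(anat_codes) + list(terr_codes) if int(cd) in bundle.legend
        }
        out.append(Finding(
            kind=kind, side=side, slice_indices=slices,
            anatomy_structures=names(anat_codes), territories=names(terr_codes),
            pair_means={k: v for k, v in pair_means.items() if k in relevant},
            volume_ml=vol_ml,
        ))
    return out


# --------------------------------------------------------------------------
# Type-II quantification
# --------------------------------------------------------------------------

@dataclass
class StructureContribution:
    code: int
    name: str
    volume_cm3: float
    percent: float


@dataclass
class RoiQuantification:
    contributions: list[StructureContribution]
    roi_volume_cm3: float

    def to_dict(self) -> dict:
        return {
            "roi_volume_cm3": self.roi_volume_cm3,
            "contributions": [vars(c) for c in self.contributions],
        }


def quantify_roi(
    roi_mask: Volume3D, labels: Volume3D, legend: dict[int, LabelInfo] | None = None
) -> RoiQuantification:
    """Volume and percentage contribution of each atlas structure to an ROI."""
    if roi_mask.shape != labels.shape:
        raise ValueError("ROI and labels must be co-registered")
    roi = roi_mask.data > 0
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    vox_cm3 = float(np.prod(roi_mask.spacing)) / 1000.0
    codes, counts = np.unique(labels.data[roi], return_counts=True)
    contribs = []
    for code, cnt in zip(codes, counts):
        info = (legend or {}).get(int(code))
        name = info.name if info else ("unlabeled" if code == 0 else str(int(code)))
        contribs.append(StructureContribution(
            int(code), name, float(cnt * vox_cm3), float(100.0 * cnt / n_roi)
        ))
    contribs.sort(key=lambda c: -c.volume_cm3)
    return RoiQuantification(contribs, float(n_roi * vox_cm3))


# --------------------------------------------------------------------------
# Thrombolysis conditions
# --------------------------------------------------------------------------

@dataclass
class ThrombolysisAssessment:
    infarct_volume_ml: float
    penumbra_volume_ml: float | None
    mismatch_ratio: float | None
    infarct_side: str
    infarct_to_MCA_ratio: float
    infarct_to_ACA_ratio: float
    infarct_to_PCA_ratio: float
    infarct_to_MCA_terminal_ratio: float
    infarct_to_MCA_penetrating_ratio: float
    exceeds_one_third: bool
    exceeds_one_half: bool

    def to_dict(self) -> dict:
        return vars(self)


def assess_thrombolysis(
    infarct_mask: Volume3D,
    penumbra_mask: Volume3D | None,
    territories: Volume3D,
    legend: dict[int, LabelInfo],
) -> ThrombolysisAssessment:
    """3D infarct/territory ratios and the diffusion-perfusion mismatch.

    The territory side is the one containing the majority of infarct voxels;
    eligibility flags use strict inequalities against 1/3 and 1/2.
    """
    if infarct_mask.shape != territories.shape:
        raise ValueError("infarct mask and territories must be co-registered")
    inf = infarct_mask.data > 0
    vox_ml = infarct_mask.voxel_volume_ml()
    inf_ml = float(inf.sum() * vox_ml)
    if inf_ml == 0:
        warnings.warn("empty infarct mask: all ratios reported as 0")

    side_counts = {"left": 0, "right": 0}
    for code in np.unique(territories.data[inf]):
        info = legend.get(int(code))
        if info and info.laterality in side_counts:
            side_counts[info.laterality] += int(
                ((territories.data == code) & inf).sum()
            )
    side = "left" if side_counts["left"] >= side_counts["right"] else "right"

    def territory_mask(base: str) -> np.ndarray:
        m = np.zeros(territories.shape, dtype=bool)
        for code, info in legend.items():
            name = info.name.removesuffix("_left").removesuffix("_right")
            if info.laterality == side and name.startswith(base):
                m |= territories.data == code
        return m

    def ratio(base: str) -> float:
        m = territory_mask(base)
        denom = int(m.sum())
        if denom == 0 or inf_ml == 0:
            return 0.0
        return float((m & inf).sum() / denom)

    r_mca = ratio("MCA")
    pen_ml = None
    mismatch = None
    if penumbra_mask is not None:
        pen_ml = float((penumbra_mask.data > 0).sum() * penumbra_mask.voxel_volume_ml())
        mismatch = pen_ml / inf_ml if inf_ml > 0 else None
    return ThrombolysisAssessment(
        infarct_volume_ml=inf_ml,
        penumbra_volume_ml=pen_ml,
        mismatch_ratio=mismatch,
        infarct_side=side,
        infarct_to_MCA_ratio=r_mca,
        infarct_to_ACA_ratio=ratio("ACA"),
        infarct_to_PCA_ratio=ratio("PCA"),
        infarct_to_MCA_terminal_ratio=ratio("MCA_terminal"),
        infarct_to_MCA_penetrating_ratio=ratio("MCA_penetrating"),
        exceeds_one_third=r_mca > 1.0 / 3.0,
        exceeds_one_half=r_mca > 0.5,
    )
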