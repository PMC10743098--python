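"""Local, regional, and global evaluation of predicted Jacobian maps.

Local/regional metrics (MAE, voxelwise Spearman, PSNR, SSIM, quartile Dice)
are computed on ``|log2 J|`` so expansion and contraction magnitudes share a
scale.  Global statistics are the whole-lung Jacobian mean ``J_mu`` and
coefficient of variation ``J_CV``.  Regional volume change uses

    dV_ROI  = (J_mu,ROI - 1) * V_ROI
    dV_ROI% = 100 * dV_ROI / dV_L

over a partition of the lung (lobes, or PRM classes from the paired-threshold
rule: -856 HU at FRC, -950 HU at TLC); by construction the dV% of a partition
sums to 100.  Cases with almost no total volume change (|J_mu - 1| < 0.02)
are flagged for exclusion from dV% summaries to avoid near-zero division.
Cohort agreement uses ordinary least squares (slope, intercept, r^2) and
Bland-Altman mean difference with 95% limits (mean +/- 1.96 sd).

Conventions (declared in report metadata): population standard deviation
(divide by n) throughout; Spearman with average ranks for ties; PSNR peak
equal to the SSIM dynamic range (5) on the |log2 J| scale, capped at 300 dB
for identical maps.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .deformation import JacobianMap
from .network import predict_jacobian
from .preprocess import PreparedCase, PreprocessConfig, prepare_case, unpad
from .training import SSIMParams, ssim_map
from .volumes import LungMask, ROILabelMap, Volume3D, crop_to_box

__all__ = [
    "LocalRegionalMetrics", "GlobalStats", "ROIVolumeChange", "AgreementSummary",
    "local_metrics", "dice_quartile", "global_stats", "roi_volume_change",
    "prm_classify", "agreement_summary", "evaluate_cohort", "MetricsReport",
    "PRM_FRC_THRESHOLD_HU", "PRM_TLC_THRESHOLD_HU", "JMU_EXCLUSION_BAND",
]

PRM_FRC_THRESHOLD_HU = -856.0
PRM_TLC_THRESHOLD_HU = -950.0
JMU_EXCLUSION_BAND = 0.02
PSNR_CAP_DB = 300.0
PRM_NAMES = {1: "normal", 2: "fsad", 3: "emphysema"}

REPORT_METADATA = {
    "scale": "|log2 J|",
    "sd_convention": "population (divide by n)",
    "spearman_ties": "average ranks",
    "psnr_peak": 5.0,
    "psnr_cap_db": PSNR_CAP_DB,
    "dice_quartile_thresholds": "per map (each map's own in-mask 25th/75th percentiles)",
}


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LocalRegionalMetrics:
    mae: float
    spearman: float          # NaN with flag when undefined (constant input)
    psnr: float
    ssim: float
    dice_low: float
    dice_high: float
    spearman_defined: bool = True
    dice_defined: bool = True


@dataclasses.dataclass
class GlobalStats:
    j_mean: float
    j_cv: float


@dataclasses.dataclass
class ROIVolumeChange:
    table: pd.DataFrame      # roi, name, volume_mm3, j_mean, dv_mm3, dv_pct
    dv_total_mm3: float
    j_mean_lung: float
    excluded: bool           # |J_mu - 1| < 0.02 exclusion rule


@dataclasses.dataclass
class AgreementSummary:
    slope: float
    intercept: float
    r2: float
    ba_mean: float
    ba_lo: float
    ba_hi: float
    n: int
    by_group: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def _abs_log2(jmap: JacobianMap) -> np.ndarray:
    return np.abs(np.asarray(jmap.Y.data, dtype=np.float64))


def local_metrics(J_ref: JacobianMap, J_pred: JacobianMap, mask,
                  ssim_params: SSIMParams | None = None) -> LocalRegionalMetrics:
    """All voxelwise/regional metrics on |log2 J| over the lung mask."""
    p = ssim_params or SSIMParams()
    m = np.asarray(getattr(mask, "data", mask)) > 0
    if not np.any(m):
        raise ValueError("empty mask")
    a = _abs_log2(J_ref)
    b = _abs_log2(J_pred)
    if a.shape != b.shape:
        raise ValueError("grid mismatch between reference and prediction")
    av, bv = a[m], b[m]
    mae = float(np.abs(av - bv).mean())
    spearman_defined = av.std() > 0 and bv.std() > 0
    if spearman_defined:
        rho = float(stats.spearmanr(av, bv).statistic)
    else:
        rho = float("nan")
    mse = float(((av - bv) ** 2).mean())
    psnr = PSNR_CAP_DB if mse == 0 else min(
        PSNR_CAP_DB, float(10.0 * np.log10(p.dynamic_range**2 / mse)))
    ssim = float(ssim_map(a, b, p)[m].mean())
    dice_low = dice_quartile(J_ref, J_pred, mask, "low")
    dice_high = dice_quartile(J_ref, J_pred, mask, "high")
    return LocalRegionalMetrics(
        mae=mae, spearman=rho, psnr=psnr, ssim=ssim,
        dice_low=dice_low, dice_high=dice_high,
        spearman_defined=bool(spearman_defined),
        dice_defined=bool(np.asarray(getattr(J_ref.J, "data"))[m].std() > 0),
    )


def dice_quartile(J_ref: JacobianMap, J_pred: JacobianMap, mask, which: str) -> float:
    """Dice overlap of each map's own lower/upper in-mask Jacobian quartile."""
    if which not in ("low", "high"):
        raise ValueError("which must be 'low' or 'high'")
    m = np.asarray(getattr(mask, "data", mask)) > 0
    if m.sum() < 4:
        raise ValueError("mask too small for quartile regions")
    regions = []
    for jmap in (J_ref, J_pred):
        j = np.asarray(jmap.J.data, dtype=np.float64)
        vals = j[m]
        if which == "low":
            thr = np.percentile(vals, 25)
            region = m & (j < thr)
        else:
            thr = np.percentile(vals, 75)
            region = m & (j > thr)
        regions.append(region)
    a, b = regions
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0  # degenerate constant map; flagged by caller
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def global_stats(J: JacobianMap, mask) -> GlobalStats:
    """Whole-lung Jacobian mean and coefficient of variation (population sd)."""
    m = np.asarray(getattr(mask, "data", mask)) > 0
    vals = np.asarray(J.J.data, dtype=np.float64)[m]
    mean = float(vals.mean())
    return GlobalStats(j_mean=mean, j_cv=float(vals.std() / mean))


def roi_volume_change(J: JacobianMap, rois: ROILabelMap, mask) -> ROIVolumeChange:
    """Per-ROI volume change and its percent of total lung volume change."""
    m = np.asarray(getattr(mask, "data", mask)) > 0
    labels = np.asarray(rois.data)
    if np.any(labels[m] == 0) or np.any(labels[~m] != 0):
        raise ValueError("ROIs do not partition the lung mask")
    j = np.asarray(J.J.data, dtype=np.float64)
    voxvol = float(np.prod(rois.spacing))
    rows = []
    for lab in sorted(int(v) for v in np.unique(labels) if v != 0):
        sel = labels == lab
        v_roi = float(sel.sum()) * voxvol
        j_mu = float(j[sel].mean())
        dv = (j_mu - 1.0) * v_roi
        rows.append({"roi": lab, "name": rois.label_table.get(lab, str(lab)),
                     "volume_mm3": v_roi, "j_mean": j_mu, "dv_mm3": dv})
    df = pd.DataFrame(rows)
    dv_total = float(df["dv_mm3"].sum())
    j_mean_lung = float(j[m].mean())
    excluded = abs(j_mean_lung - 1.0) < JMU_EXCLUSION_BAND
    df["dv_pct"] = 100.0 * df["dv_mm3"] / dv_total if dv_total != 0 else np.nan
    return ROIVolumeChange(table=df, dv_total_mm3=dv_total,
                           j_mean_lung=j_mean_lung, excluded=bool(excluded))


def prm_classify(i_frc_aligned: Volume3D, i_tlc: Volume3D, mask) -> ROILabelMap:
    """Parametric response mapping on voxelwise-corresponding HU pairs.

    emphysema: TLC < -950 and FRC < -856; fSAD: TLC >= -950 and FRC < -856;
    normal: FRC >= -856.  The two inputs must already be in voxelwise
    correspondence (exact for phantoms; callers supply pre-aligned volumes
    for real data).
    """
    m = np.asarray(getattr(mask, "data", mask)) > 0
    frc = np.asarray(i_frc_aligned.data, dtype=np.float64)
    tlc = np.asarray(i_tlc.data, dtype=np.float64)
    if frc.shape != tlc.shape:
        raise ValueError("PRM inputs must share a grid")
    lab = np.zeros(frc.shape, dtype=np.uint16)
    trapped = frc < PRM_FRC_THRESHOLD_HU
    emph = trapped & (tlc < PRM_TLC_THRESHOLD_HU)
    fsad = trapped & ~emph
    lab[m & ~trapped] = 1
    lab[m & fsad] = 2
    lab[m & emph] = 3
    return ROILabelMap(lab, dict(PRM_NAMES), i_tlc.spacing, i_tlc.origin)


def agreement_summary(pairs, groups=None) -> AgreementSummary:
    """OLS regression (predicted vs. reference) plus Bland-Altman limits.

    ``pairs`` is a sequence of (predicted, reference) scalars.  Differences
    for Bland-Altman are predicted - reference; limits are mean +/- 1.96 sd
    (population sd).  With ``groups``, per-group Bland-Altman statistics are
    reported as well.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (predicted, reference) pairs")
    pred, ref = arr[:, 0], arr[:, 1]
    if ref.std() == 0:
        raise ValueError("zero variance in reference values")
    res = stats.linregress(ref, pred)
    diffs = pred - ref
    ba_mean = float(diffs.mean())
    sd = float(diffs.std())
    by_group = None
    if groups is not None:
        groups = np.asarray(groups)
        rows = []
        for g in pd.unique(groups):
            d = diffs[groups == g]
            rows.append({"group": g, "n": int(d.size), "ba_mean": float(d.mean()),
                         "ba_lo": float(d.mean() - 1.96 * d.std()),
                         "ba_hi": float(d.mean() + 1.96 * d.std())})
        by_group = pd.DataFrame(rows)
    return AgreementSummary(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), ba_mean=ba_mean,
        ba_lo=ba_mean - 1.96 * sd, ba_hi=ba_mean + 1.96 * sd,
        n=int(arr.shape[0]), by_group=by_group,
    )


# ---------------------------------------------------------------------------
# Cohort evaluation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MetricsReport:
    per_case: pd.DataFrame          # one row per case x arm: local/regional/global
    dv_rows: pd.DataFrame           # one row per case x arm x roi-kind x roi
    agreement: pd.DataFrame         # per arm: J_mu and lobar dV% regressions
    prm_bland_altman: pd.DataFrame  # per arm x PRM class: BA mean and limits
    metadata: dict


def _warp_intensity(case, space: str) -> Volume3D:
    """Sample the opposite frame's HU image at corresponding points.

    For the FRC frame this is ``I_TLC(h(x))``; for TLC, ``I_FRC(h^-1(y))``.
    Trilinear interpolation on the analytic correspondence.
    """
    if space == "FRC":
        src, mapping, template = case.I_TLC, case.h, case.I_FRC
    else:
        src, mapping, template = case.I_FRC, case.h.inverse(), case.I_TLC
    pts = template.physical_grid()
    mapped = mapping(pts.reshape(-1, 3))
    idx = (mapped - np.asarray(src.origin)) / np.asarray(src.spacing)
    vals = ndimage.map_coordinates(np.asarray(src.data, dtype=np.float64),
                                   idx.T, order=1, mode="nearest")
    return Volume3D(vals.reshape(template.shape).astype(np.float32),
                    template.spacing, template.origin, intensity_kind="HU")


def _case_frame_data(case, prepared: PreparedCase, space: str):
    """Cropped reference J map, mask, lobes and PRM ROIs for one output space."""
    box = prepared.box
    y_ref = unpad(prepared.target(space), prepared.pads)
    m = unpad(prepared.mask(space), prepared.pads)
    spacing = prepared.spacing
    mask = LungMask((m > 0).astype(np.uint8), spacing)
    Yv = Volume3D(y_ref.astype(np.float32), spacing, intensity_kind="log2_jacobian")
    j_ref = JacobianMap.from_Y(Yv, frame=space)
    lobes_full = case.lobes_frc if space == "FRC" else case.lobes_tlc
    lobes = ROILabelMap(crop_to_box(np.asarray(lobes_full.data), box),
                        dict(lobes_full.label_table), spacing)
    native = case.I_FRC if space == "FRC" else case.I_TLC
    warped = _warp_intensity(case, space)
    if space == "FRC":
        frc_hu, tlc_hu = native, warped
    else:
        frc_hu, tlc_hu = warped, native
    prm = prm_classify(
        Volume3D(crop_to_box(np.asarray(frc_hu.data), box), spacing, intensity_kind="HU"),
        Volume3D(crop_to_box(np.asarray(tlc_hu.data), box), spacing, intensity_kind="HU"),
        mask,
    )
    return j_ref, mask, lobes, prm


def evaluate_cohort(
    results: dict,
    cases,
    preprocess_cfg: PreprocessConfig | None = None,
    ssim_params: SSIMParams | None = None,
    include_controls: bool = False,
) -> MetricsReport:
    """Evaluate trained arms on held-out cases.

    ``results`` maps arm name to a TrainResult (or any object with ``arm``
    and ``model``).  With ``include_controls`` the ground truth is also fed
    through the pipeline as its own prediction (identity rows, arm suffix
    ``:control``).
    """
    ssim_params = ssim_params or SSIMParams()
    per_case_rows = []
    dv_rows = []
    jmu_pairs: dict[str, list] = {}
    lobar_pairs: dict[str, list] = {}
    prm_pairs: dict[str, list] = {}
    prm_groups: dict[str, list] = {}

    for case in cases:
        divisor = next(iter(results.values())).model.cfg.divisor
        prepared = prepare_case(case, preprocess_cfg, multiple=divisor)
        frames = {s: _case_frame_data(case, prepared, s) for s in ("FRC", "TLC")}
        arm_items = list(results.items())
        if include_controls:
            arm_items += [(f"{name}:control", None) for name in results]
        for name, res in arm_items:
            if res is None:
                base = results[name.split(":")[0]]
                space = base.arm.output_space
                j_ref, mask, lobes, prm = frames[space]
                j_pred = j_ref
            else:
                space = res.arm.output_space
                j_ref, mask, lobes, prm = frames[space]
                j_pred = predict_jacobian(res.model, prepared, res.arm)
            loc = local_metrics(j_ref, j_pred, mask, ssim_params)
            g_pred = global_stats(j_pred, mask)
            g_ref = global_stats(j_ref, mask)
            per_case_rows.append({
                "case_id": case.case_id, "arm": name, "output_space": space,
                "mae": loc.mae, "spearman": loc.spearman, "psnr": loc.psnr,
                "ssim": loc.ssim, "dice_low": loc.dice_low, "dice_high": loc.dice_high,
                "j_mean": g_pred.j_mean, "j_cv": g_pred.j_cv,
                "j_mean_ref": g_ref.j_mean, "j_cv_ref": g_ref.j_cv,
                "effort_true": getattr(case, "effort_true", np.nan),
            })
            jmu_pairs.setdefault(name, []).append((g_pred.j_mean, g_ref.j_mean))
            for kind, roimap in (("lobe", lobes), ("prm", prm)):
                rvc_pred = roi_volume_change(j_pred, roimap, mask)
                rvc_ref = roi_volume_change(j_ref, roimap, mask)
                merged = rvc_pred.table.merge(
                    rvc_ref.table[["roi", "dv_pct", "j_mean"]], on="roi",
                    suffixes=("", "_ref"))
                for _, row in merged.iterrows():
                    dv_rows.append({
                        "case_id": case.case_id, "arm": name, "roi_kind": kind,
                        "roi": int(row["roi"]), "name": row["name"],
                        "dv_pct": row["dv_pct"], "dv_pct_ref": row["dv_pct_ref"],
                        "excluded": rvc_ref.excluded,
                    })
                    if not rvc_ref.excluded and np.isfinite(row["dv_pct"]):
                        if kind == "lobe":
                            lobar_pairs.setdefault(name, []).append(
                                (row["dv_pct"], row["dv_pct_ref"]))
                        else:
                            prm_pairs.setdefault(name, []).append(
                                (row["dv_pct"], row["dv_pct_ref"]))
                            prm_groups.setdefault(name, []).append(row["name"])

    agreement_rows = []
    for name, pairs in jmu_pairs.items():
        if len(pairs) >= 3 and np.asarray(pairs)[:, 1].std() > 0:
            s = agreement_summary(pairs)
            agreement_rows.append({"arm": name, "quantity": "j_mean", **_summary_row(s)})
    for name, pairs in lobar_pairs.items():
        if len(pairs) >= 3 and np.asarray(pairs)[:, 1].std() > 0:
            s = agreement_summary(pairs)
            agreement_rows.append({"arm": name, "quantity": "lobar_dv_pct", **_summary_row(s)})
    ba_rows = []
    for name, pairs in prm_pairs.items():
        if len(pairs) >= 3 and np.asarray(pairs)[:, 1].std() > 0:
            s = agreement_summary(pairs, groups=prm_groups[name])
            agreement_rows.append({"arm": name, "quantity": "prm_dv_pct", **_summary_row(s)})
            if s.by_group is not None:
                for _, row in s.by_group.iterrows():
                    ba_rows.append({"arm": name, **row.to_dict()})

    return MetricsReport(
        per_case=pd.DataFrame(per_case_rows),
        dv_rows=pd.DataFrame(dv_rows),
        agreement=pd.DataFrame(agreement_rows),
        prm_bland_altman=pd.DataFrame(ba_rows),
        metadata=dict(REPORT_METADATA),
    )


def _summary_row(s: AgreementSummary) -> dict:
    return {"slope": s.slope, "intercept": s.intercept, "r2": s.r2,
            "ba_mean": s.ba_mean, "ba_lo": s.ba_lo, "ba_hi": s.ba_hi, "n": s.n}
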