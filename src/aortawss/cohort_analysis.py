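"""Per-subject segment summaries, abnormality thresholds, and cohort stats.

For each subject and each of the five aortic segments the pipeline
reports: maximum effective diameter normalized by body surface area,
average velocity and average |WSS| at the segment's peak-flow timeframe
(peak velocity / peak WSS), and area-weighted node means of TAWSS, OSI
and RRT.  Abnormality thresholds are mean -/+ 2 SD of a reference
cohort (low WSS, high OSI, high RRT), and the exposed fraction of a
segment's wall area beyond a threshold quantifies local abnormality.
Two-group comparisons are gated by a Shapiro-Wilk normality test: a
two-tailed unpaired t-test when both groups are normal, a two-sided
Wilcoxon rank-sum test otherwise, with Bonferroni-corrected
significance at p < 0.025 (two cohort contrasts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from aortawss.flow_io import (
    MaskVolume,
    VelocityField4D,
    correct_background_offset,
    load_velocity_dataset,
    unwrap_phase,
    voxel_to_world,
)
from aortawss.geometry import (
    Centerline,
    LandmarkSet,
    SEGMENT_NAMES,
    SegmentLabels,
    SurfaceMesh,
    _label_arclengths,
    compute_centerline,
    extract_surface,
    partition_segments,
    project_to_centerline,
    segment_flow_and_diameter,
)
from aortawss.phantom import PhantomSpec, build_phantom
from aortawss.wss_core import (
    HemodynamicMaps,
    ViscosityModel,
    WSSConfig,
    WSSVectorField,
    compute_hemodynamic_maps,
    compute_wss_field,
)

COHORTS = ("AAA", "elderly", "young")
METRICS = ("diameter_over_bsa", "peak_velocity", "peak_wss", "tawss", "osi", "rrt")
ALPHA_BONFERRONI = 0.025  # 0.05 / 2 cohort contrasts
SHAPIRO_ALPHA = 0.05


@dataclass
class SubjectInfo:
    subject_id: str
    cohort: str
    bsa_m2: float

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort '{self.cohort}'")
        if self.bsa_m2 <= 0:
            raise ValueError("BSA must be positive")


@dataclass
class SegmentSummary:
    """Per-segment scalar metrics for one subject (rows = segments)."""

    subject: SubjectInfo
    table: pd.DataFrame  # index SEGMENT_NAMES, columns METRICS + tf_peak


@dataclass
class GroupComparison:
    metric: str
    segment: str
    test_used: str          # "t" or "wilcoxon"
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool
    summary_a: str
    summary_b: str


@dataclass
class SubjectResult:
    """Everything computed for one subject, kept for local analyses."""

    summary: SegmentSummary
    mesh: SurfaceMesh
    labels: SegmentLabels
    maps: HemodynamicMaps
    wss: WSSVectorField
    peak_wss_node_Pa: dict  # segment -> per-node |WSS| at that segment's TF_peak
    centerline: Centerline
    flows: dict
    thrombus_nodes: Optional[np.ndarray] = None  # bool per node


# ---------------------------------------------------------------------------
# summaries


def _weighted_mean(values, weights):
    ok = np.isfinite(values)
    if not np.any(ok):
        return float("nan")
    return float(np.average(values[ok], weights=weights[ok]))


def summarize_segments(
    maps: HemodynamicMaps,
    wss: WSSVectorField,
    fld: VelocityField4D,
    lumen: MaskVolume,
    labels: SegmentLabels,
    flows: dict,
    mesh: SurfaceMesh,
    centerline: Centerline,
    subject: SubjectInfo,
    weighting: str = "area",
) -> SegmentSummary:
    """Segment-level metric table for one subject.

    Node means are area-weighted by default (``weighting='count'``
    gives plain node means); missing-flagged nodes are excluded.  Peak
    velocity is the mean lumen-voxel speed within the segment at that
    segment's TF_peak, in m/s.
    """
    if weighting not in ("area", "count"):
        raise ValueError("weighting must be 'area' or 'count'")
    w_all = mesh.node_area_mm2 if weighting == "area" else np.ones(mesh.n_nodes)
    mag = wss.magnitude()  # (N, nt)

    # assign lumen voxels to segments through the centerline arclength
    vox = np.stack(np.nonzero(lumen.data), axis=1).astype(np.float64)
    vox_world = voxel_to_world(lumen.affine, vox)
    vox_s = project_to_centerline(centerline, vox_world)
    vox_labels = _label_arclengths(vox_s, labels.intervals)
    speed = fld.speed()[lumen.data]  # (n_lumen, nt), cm/s

    rows = {}
    for si, seg in enumerate(SEGMENT_NAMES):
        nodes = labels.nodes_of(seg)
        nodes = nodes[~wss.missing[nodes]]
        tf_peak = flows[seg].tf_peak
        row = dict.fromkeys(METRICS, float("nan"))
        row["tf_peak"] = tf_peak
        row["diameter_over_bsa"] = flows[seg].max_diameter_mm / subject.bsa_m2
        in_seg = vox_labels == si
        if np.any(in_seg):
            row["peak_velocity"] = float(speed[in_seg, tf_peak].mean()) / 100.0
        if nodes.size:
            w = w_all[nodes]
            row["peak_wss"] = _weighted_mean(mag[nodes, tf_peak], w)
            row["tawss"] = _weighted_mean(maps.tawss_Pa[nodes], w)
            row["osi"] = _weighted_mean(maps.osi[nodes], w)
            row["rrt"] = _weighted_mean(maps.rrt[nodes], w)
        rows[seg] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(SEGMENT_NAMES)]
    return SegmentSummary(subject=subject, table=table)


# ---------------------------------------------------------------------------
# thresholds and exposure


def threshold_from_moments(mean: float, sd: float, direction: str) -> float:
    """mean - 2 SD (``'low'``, floored at 0) or mean + 2 SD (``'high'``)."""
    if direction == "low":
        return max(mean - 2.0 * sd, 0.0)
    if direction == "high":
        return mean + 2.0 * sd
    raise ValueError("direction must be 'low' or 'high'")


def reference_thresholds(values, direction: str) -> float:
    """Abnormality threshold from reference-cohort values (sample SD, n-1)."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValueError("need at least 3 finite reference values")
    return threshold_from_moments(
        float(values.mean()), float(values.std(ddof=1)), direction
    )


def exposure_fraction(
    node_map: np.ndarray,
    threshold: float,
    direction: str,
    labels: SegmentLabels,
    node_area_mm2: np.ndarray,
    segment: str = "IAA",
) -> float:
    """Percent of a segment's wall area strictly beyond a threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    nodes = labels.nodes_of(segment)
    if nodes.size == 0:
        raise ValueError(f"segment '{segment}' has no surface nodes")
    vals = node_map[nodes]
    area = node_area_mm2[nodes]
    ok = np.isfinite(vals)
    vals, area = vals[ok], area[ok]
    if direction == "low":
        beyond = vals < threshold
    elif direction == "high":
        beyond = vals > threshold
    else:
        raise ValueError("direction must be 'low' or 'high'")
    frac = 100.0 * float(area[beyond].sum()) / float(area.sum())
    return float(np.clip(frac, 0.0, 100.0))


# ---------------------------------------------------------------------------
# thrombus masking


def thrombus_node_mask(mesh: SurfaceMesh, thrombus: MaskVolume) -> np.ndarray:
    """Surface nodes at the lumen/thrombus interface.

    A node belongs to the interface when it lies within one voxel
    diagonal of a thrombus voxel center.
    """
    vox = np.stack(np.nonzero(thrombus.data), axis=1).astype(np.float64)
    if vox.size == 0:
        return np.zeros(mesh.n_nodes, dtype=bool)
    centers = voxel_to_world(thrombus.affine, vox)
    spacing = np.linalg.norm(thrombus.affine[:3, :3], axis=0)
    d, _ = cKDTree(centers).query(mesh.nodes)
    return d <= float(np.linalg.norm(spacing))


def thrombus_free_comparison(
    maps: HemodynamicMaps,
    wss: WSSVectorField,
    labels: SegmentLabels,
    node_area_mm2: np.ndarray,
    thrombus_nodes: np.ndarray,
    tf_peak: int,
) -> dict:
    """Whole-IAA vs thrombus-free-wall area-weighted means per metric.

    Returns ``{metric: (whole, thrombus_free)}`` for peak WSS, TAWSS,
    OSI and RRT of one subject.  The thrombus interface nodes must be a
    strict subset of the IAA nodes.
    """
    iaa = labels.nodes_of("IAA")
    iaa = iaa[~wss.missing[iaa]]
    if iaa.size == 0:
        raise ValueError("IAA has no usable surface nodes")
    thromb = np.asarray(thrombus_nodes, dtype=bool)
    if np.any(thromb & (labels.labels != SEGMENT_NAMES.index("IAA"))):
        raise ValueError("thrombus nodes must lie within the IAA")
    free = iaa[~thromb[iaa]]
    if free.size == 0:
        raise ValueError("thrombus covers the whole IAA wall")
    mag = wss.magnitude()
    per_metric = {}
    for metric, node_map in (
        ("peak_wss", mag[:, tf_peak]),
        ("tawss", maps.tawss_Pa),
        ("osi", maps.osi),
        ("rrt", maps.rrt),
    ):
        whole = _weighted_mean(node_map[iaa], node_area_mm2[iaa])
        excl = _weighted_mean(node_map[free], node_area_mm2[free])
        per_metric[metric] = (whole, excl)
    return per_metric


# ---------------------------------------------------------------------------
# two-group statistics


def _is_normal(values: np.ndarray) -> bool:
    if np.ptp(values) == 0:
        return False  # degenerate: no variance
    return stats.shapiro(values).pvalue > SHAPIRO_ALPHA


def _summarize_group(values: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{values.mean():.3g} ± ({values.std(ddof=1):.3g})"
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:.3g} [{q3 - q1:.3g}]"


def compare_groups(
    values_a,
    values_b,
    alpha_bonferroni: float = ALPHA_BONFERRONI,
    metric: str = "",
    segment: str = "",
) -> GroupComparison:
    """Shapiro-Wilk-gated two-group comparison.

    Both groups normal at alpha 0.05 -> two-tailed unpaired t-test;
    otherwise two-sided Wilcoxon rank-sum.  Group summaries follow the
    same gate: mean +/- (SD) when normal, median [IQR] when not.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 finite values")
    degenerate = np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]
    normal_a, normal_b = _is_normal(a), _is_normal(b)
    if degenerate:
        test, stat, p = "wilcoxon", 0.0, 1.0
    elif normal_a and normal_b:
        res = stats.ttest_ind(a, b)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.ranksums(a, b)
        test, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    return GroupComparison(
        metric=metric,
        segment=segment,
        test_used=test,
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha_bonferroni),
        degenerate=bool(degenerate),
        summary_a=_summarize_group(a, normal_a),
        summary_b=_summarize_group(b, normal_b),
    )


# ---------------------------------------------------------------------------
# per-subject pipeline


def analyze_subject(
    fld: VelocityField4D,
    masks: dict,
    landmarks,
    subject: SubjectInfo,
    wss_config: Optional[WSSConfig] = None,
    viscosity: Optional[ViscosityModel] = None,
    preprocess: bool = True,
    offset_order: int = 4,
    weighting: str = "area",
    station_step_mm: float = 2.0,
) -> SubjectResult:
    """Run the full chain for one subject.

    Preprocessing (phase unwrap, then background-offset correction when
    a static-tissue mask is present) -> surface + centerline ->
    five-segment partition -> section metrics -> WSS vectors ->
    TAWSS/OSI/RRT maps -> segment summary.
    """
    wss_config = wss_config or WSSConfig()
    viscosity = viscosity or ViscosityModel()
    if isinstance(landmarks, dict):
        landmarks = LandmarkSet.from_dict(landmarks)
    lumen = masks["lumen"]
    if preprocess:
        fld, _ = unwrap_phase(fld)
        if "static_tissue" in masks:
            fld, _ = correct_background_offset(
                fld, masks["static_tissue"], order=offset_order
            )
    mesh = extract_surface(lumen)
    centerline = compute_centerline(lumen, landmarks.valve, landmarks.iliac)
    labels = partition_segments(mesh, centerline, landmarks)
    flows = segment_flow_and_diameter(
        fld, lumen, centerline, labels, station_step_mm=station_step_mm
    )
    wss = compute_wss_field(fld, mesh, wss_config, viscosity, subject.cohort)
    maps = compute_hemodynamic_maps(wss, config=wss_config)
    summary = summarize_segments(
        maps, wss, fld, lumen, labels, flows, mesh, centerline, subject,
        weighting=weighting,
    )
    mag = wss.magnitude()
    peak_node = {seg: mag[:, flows[seg].tf_peak] for seg in SEGMENT_NAMES}
    thrombus_nodes = None
    if "thrombus" in masks:
        thrombus_nodes = thrombus_node_mask(mesh, masks["thrombus"])
    return SubjectResult(
        summary=summary,
        mesh=mesh,
        labels=labels,
        maps=maps,
        wss=wss,
        peak_wss_node_Pa=peak_node,
        centerline=centerline,
        flows=flows,
        thrombus_nodes=thrombus_nodes,
    )


# ---------------------------------------------------------------------------
# cohort study


def summaries_long_table(results: dict) -> pd.DataFrame:
    """Long-form table (subject, cohort, segment, metric, value)."""
    rows = []
    for sid, res in results.items():
        info = res.summary.subject
        for seg in SEGMENT_NAMES:
            for metric in METRICS:
                rows.append(
                    {
                        "subject": sid,
                        "cohort": info.cohort,
                        "segment": seg,
                        "metric": metric,
                        "value": res.summary.table.loc[seg, metric],
                    }
                )
    return pd.DataFrame(rows)


def cohort_comparisons(long: pd.DataFrame) -> list[GroupComparison]:
    """All metric x segment contrasts: AAA vs elderly, elderly vs young."""
    out = []
    for (name_a, name_b) in (("AAA", "elderly"), ("elderly", "young")):
        if not {(name_a), (name_b)} <= set(long["cohort"].unique()):
            continue
        for metric in METRICS:
            for seg in SEGMENT_NAMES:
                sel = (long["metric"] == metric) & (long["segment"] == seg)
                a = long.loc[sel & (long["cohort"] == name_a), "value"]
                b = long.loc[sel & (long["cohort"] == name_b), "value"]
                cmp = compare_groups(a, b, metric=metric, segment=seg)
                cmp.metric = f"{metric}"
                cmp.segment = seg
                out.append((f"{name_a}_vs_{name_b}", cmp))
    return out


def study_thresholds(
    results: dict,
    reference_cohort: str = "elderly",
    pooling: str = "subject",
    segment: str = "IAA",
) -> dict:
    """Low-WSS / high-OSI / high-RRT thresholds from the reference cohort.

    ``pooling='subject'`` uses per-subject segment averages;
    ``pooling='node'`` pools all reference-cohort surface nodes of the
    segment.  The two levels can give different thresholds; both are
    supported because the appropriate level is a study design choice.
    """
    if pooling not in ("subject", "node"):
        raise ValueError("pooling must be 'subject' or 'node'")
    ref = {
        sid: r for sid, r in results.items()
        if r.summary.subject.cohort == reference_cohort
    }
    if not ref:
        raise ValueError(f"no subjects in reference cohort '{reference_cohort}'")
    spec = {"peak_wss": "low", "osi": "high", "rrt": "high"}
    out = {}
    for metric, direction in spec.items():
        if pooling == "subject":
            values = [r.summary.table.loc[segment, metric] for r in ref.values()]
        else:
            values = []
            for r in ref.values():
                nodes = r.labels.nodes_of(segment)
                nodes = nodes[~r.wss.missing[nodes]]
                node_map = {
                    "peak_wss": r.peak_wss_node_Pa[segment],
                    "osi": r.maps.osi,
                    "rrt": r.maps.rrt,
                }[metric]
                values.extend(node_map[nodes].tolist())
        out[metric] = {
            "direction": direction,
            "threshold": reference_thresholds(values, direction),
        }
    return out


def study_exposures(results: dict, thresholds: dict, segment: str = "IAA") -> pd.DataFrame:
    """Per-subject exposed wall-area percentages in one segment."""
    rows = []
    for sid, r in results.items():
        for metric, spec in thresholds.items():
            node_map = {
                "peak_wss": r.peak_wss_node_Pa[segment],
                "osi": r.maps.osi,
                "rrt": r.maps.rrt,
            }[metric]
            rows.append(
                {
                    "subject": sid,
                    "cohort": r.summary.subject.cohort,
                    "metric": metric,
                    "threshold": spec["threshold"],
                    "exposure_pct": exposure_fraction(
                        node_map, spec["threshold"], spec["direction"],
                        r.labels, r.mesh.node_area_mm2, segment,
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_phantom_study(
    cohort_specs: dict,
    n_subjects: dict,
    base_seed: int = 0,
    bsa_m2: float = 2.0,
    reference_cohort: str = "elderly",
    threshold_pooling: str = "subject",
    preprocess: bool = False,
    **analyze_kwargs,
) -> dict:
    """Generate and analyze a synthetic multi-cohort study.

    ``cohort_specs`` maps cohort name to a template :class:`PhantomSpec`
    whose seed is replaced per subject (derived deterministically from
    ``base_seed``).  Returns results, long table, comparisons,
    thresholds and exposures.
    """
    results = {}
    for ci, (cohort, template) in enumerate(sorted(cohort_specs.items())):
        for j in range(n_subjects[cohort]):
            seed = (base_seed * 100003 + ci * 1009 + j) % (2**31 - 1)
            ds = build_phantom(replace(template, seed=seed))
            sid = f"{cohort}{j:02d}"
            subject = SubjectInfo(subject_id=sid, cohort=cohort, bsa_m2=bsa_m2)
            masks = {"lumen": ds.lumen, "static_tissue": ds.static_tissue}
            if ds.thrombus is not None:
                masks["thrombus"] = ds.thrombus
            results[sid] = analyze_subject(
                ds.field, masks, ds.landmarks, subject,
                preprocess=preprocess, **analyze_kwargs,
            )
    long = summaries_long_table(results)
    comparisons = cohort_comparisons(long)
    thresholds = None
    exposures = None
    if any(r.summary.subject.cohort == reference_cohort for r in results.values()):
        thresholds = study_thresholds(
            results, reference_cohort, pooling=threshold_pooling
        )
        exposures = study_exposures(results, thresholds)
    return {
        "results": results,
        "long": long,
        "comparisons": comparisons,
        "thresholds": thresholds,
        "exposures": exposures,
    }


# ---------------------------------------------------------------------------
# end-to-end file-based pipeline


def _comparison_frame(comparisons) -> pd.DataFrame:
    rows = []
    for contrast, c in comparisons:
        rows.append(
            {
                "contrast": contrast,
                "metric": c.metric,
                "segment": c.segment,
                "test": c.test_used,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "significant": c.significant,
                "group_a": c.summary_a,
                "group_b": c.summary_b,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute a full cohort study from a configuration mapping.

    The config lists subjects with dataset directories (as written by
    :func:`aortawss.flow_io.write_velocity_dataset`), cohort labels,
    BSA and landmark coordinates, plus optional preprocessing and
    weighting options.  Writes a segment x metric results table with
    the two cohort contrasts, an exposure table and a JSON manifest;
    output is deterministic for fixed inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    opts = config.get("options", {})
    results = {}
    failures = {}
    for sub in config["subjects"]:
        sid = sub["subject_id"]
        try:
            fld, masks = load_velocity_dataset(sub["path"])
            landmarks = {
                k: np.asarray(v, dtype=np.float64)
                for k, v in sub["landmarks"].items()
            }
            subject = SubjectInfo(
                subject_id=sid, cohort=sub["cohort"], bsa_m2=sub["bsa_m2"]
            )
            results[sid] = analyze_subject(
                fld, masks, landmarks, subject,
                preprocess=opts.get("preprocess", True),
                offset_order=opts.get("offset_order", 4),
                weighting=opts.get("weighting", "area"),
            )
        except Exception as exc:  # recorded, study continues
            failures[sid] = f"{type(exc).__name__}: {exc}"
    if not results:
        raise ValueError("no subject could be analyzed")

    long = summaries_long_table(results)
    long.to_csv(out_dir / "segment_summaries.csv", index=False)
    comparisons = cohort_comparisons(long)
    _comparison_frame(comparisons).to_csv(out_dir / "cohort_table.csv", index=False)

    reference = opts.get("reference_cohort", "elderly")
    if any(r.summary.subject.cohort == reference for r in results.values()):
        thresholds = study_thresholds(
            results, reference, pooling=opts.get("threshold_pooling", "subject")
        )
        exposures = study_exposures(results, thresholds)
        exposures.to_csv(out_dir / "exposure_table.csv", index=False)
    else:
        thresholds, exposures = None, None

    import importlib.metadata

    try:
        version = importlib.metadata.version("aortawss")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    manifest = {
        "package_version": version,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_subjects": len(results),
        "failed_subjects": failures,
        "thresholds": thresholds,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "results": results,
        "long": long,
        "comparisons": comparisons,
        "thresholds": thresholds,
        "exposures": exposures,
        "manifest": manifest,
    }
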