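"""End-to-end benchmark runs: phantom cohort -> distortion -> standardisation
-> four-criterion evaluation, reproducible from a config + seed.

Every run writes one directory containing a manifest (config, seeds,
package version), per-method transform JSONs, and four CSV reports, one per
evaluation criterion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    cdf_abs_error, correlation_maintenance, interface_boundary_intensity,
    pitman_morgan, voxelwise_intensity_difference, wilcoxon_signed_rank,
)
from .histogram import (
    compute_histogram, cumulative_distribution, detect_modes, smooth_histogram,
)
from .phantom import (
    DEFAULT_TISSUE_SDS, DistortionSpec, PhantomSpec, PhantomSubject,
    apply_distortion, generate_cohort, generate_phantom, phantom_rois,
)
from .segmentation import clean_roi, fuzzy_segment, hard_labels, tissue_stats
from .transforms import (
    ROIMedians, TransformFunction, apply_transform, build_chm, build_nhm,
    build_phm, build_rls, build_sps, identity_transform, serialize_transform,
)
from .volume_io import I_MAX, I_MIN, IntensityVolume, TissueLabelMap, write_volume

KNOWN_METHODS = ("identity", "phm", "nhm", "chm", "rls", "sps")


@dataclass
class RunConfig:
    """Configuration of one benchmark run."""

    methods: tuple[str, ...] = ("phm", "nhm", "chm", "rls", "sps")
    n_targets: int = 10
    seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    intensity_min: float = I_MIN
    intensity_max: float = I_MAX
    distortion_kind: str = "study"
    slope_range: tuple[float, float] = (0.95, 1.05)
    offset_range: tuple[float, float] = (-100.0, 100.0)
    # "study" kind: per-target GM/WM median shifts in the outermost-decile
    # band of the study sample (GM median SD 76, WM median SD 58)
    gm_shift_range: tuple[float, float] = (60.0, 120.0)
    wm_shift_range: tuple[float, float] = (45.0, 90.0)
    noiseless: bool = False
    quantize: bool = False
    write_volumes: bool = False
    out_dir: str = "mristand_run"
    hypothalamus_radius_vox: int = 5
    wm_shell_radius_vox: int = 7

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def validate_config(cfg: RunConfig) -> list[str]:
    """Human-readable configuration issues (empty list = valid)."""
    issues: list[str] = []
    for m in cfg.methods:
        if m.lower() not in KNOWN_METHODS:
            issues.append(f"unknown method {m!r} (choose from {KNOWN_METHODS})")
    if cfg.n_targets < 1:
        issues.append("n_targets must be >= 1")
    if not cfg.intensity_min < cfg.intensity_max:
        issues.append("intensity_min must be < intensity_max")
    if len(cfg.grid_shape) != 3 or any(s < 16 for s in cfg.grid_shape):
        issues.append("grid_shape must be three dimensions of at least 16 voxels")
    if cfg.slope_range[0] <= 0 or cfg.slope_range[0] > cfg.slope_range[1]:
        issues.append("slope_range must be positive and ordered")
    if cfg.offset_range[0] > cfg.offset_range[1]:
        issues.append("offset_range must be ordered")
    if cfg.wm_shell_radius_vox <= cfg.hypothalamus_radius_vox:
        issues.append("wm_shell_radius_vox must exceed hypothalamus_radius_vox")
    if cfg.distortion_kind not in ("identity", "offset", "linear", "study"):
        issues.append("distortion_kind must be identity, offset, linear, or study")
    return issues


def sample_study_distortion(
    rng: np.random.Generator,
    gm_shift_range: tuple[float, float] = (60.0, 120.0),
    wm_shift_range: tuple[float, float] = (45.0, 90.0),
    gm_anchor: float = 1907.0,
    wm_anchor: float = 3246.0,
) -> DistortionSpec:
    """A linear interscan distortion emulating an extreme-decile target image.

    GM and WM median shifts are drawn (magnitude uniform in the given bands,
    signs independent) and converted to the line through the two shifted
    tissue anchors — the "over/underexposure scaling with intensity" model.
    """
    dg = float(rng.uniform(*gm_shift_range)) * (1 if rng.random() < 0.5 else -1)
    dw = float(rng.uniform(*wm_shift_range)) * (1 if rng.random() < 0.5 else -1)
    m = 1.0 + (dw - dg) / (wm_anchor - gm_anchor)
    n = dg - (m - 1.0) * gm_anchor
    return DistortionSpec("linear", {"slope": m, "offset": n})


# ---------------------------------------------------------------------------
# Transform construction per method
# ---------------------------------------------------------------------------

@dataclass
class ReferenceContext:
    """Everything a standardisation method may need about the reference."""

    volume: IntensityVolume
    labels: TissueLabelMap            # segmentation labels of the reference
    spec: PhantomSpec
    modes: tuple[float, float]
    brain_cdf: object
    roi_medians: tuple[float, float]  # (GM, WM) cleaned-ROI medians
    tissue_means: tuple[float, float, float]


def _segment_labels(vol: IntensityVolume) -> TissueLabelMap:
    return hard_labels(fuzzy_segment(vol))


def _image_modes(vol: IntensityVolume) -> tuple[float, float]:
    h = compute_histogram(vol)
    gm, wm = detect_modes(smooth_histogram(h))
    return gm.intensity, wm.intensity


def _roi_medians(vol, labels, spec, min_voxels=50) -> tuple[float, float]:
    gm_roi, wm_roi = phantom_rois(labels, spec)
    gm_roi = clean_roi(gm_roi, labels, min_voxels=min_voxels)
    wm_roi = clean_roi(wm_roi, labels, min_voxels=min_voxels)
    return (
        float(np.median(vol.data[gm_roi.mask])),
        float(np.median(vol.data[wm_roi.mask])),
    )


def make_reference_context(
    volume: IntensityVolume, spec: PhantomSpec
) -> ReferenceContext:
    labels = _segment_labels(volume)
    stats = tissue_stats(volume, labels)
    return ReferenceContext(
        volume=volume,
        labels=labels,
        spec=spec,
        modes=_image_modes(volume),
        brain_cdf=cumulative_distribution(compute_histogram(volume)),
        roi_medians=_roi_medians(volume, labels, spec),
        tissue_means=(stats.mean["CSF"], stats.mean["GM"], stats.mean["WM"]),
    )


def build_method_transform(
    method: str,
    target: IntensityVolume,
    target_labels: TissueLabelMap,
    target_spec: PhantomSpec,
    ref: ReferenceContext,
) -> TransformFunction:
    """Build one method's transform from a target image and the reference."""
    method = method.lower()
    domain = (target.intensity_min, target.intensity_max)
    if method == "identity":
        return identity_transform(domain)
    if method in ("phm", "nhm"):
        t_modes = _image_modes(target)
        builder = build_phm if method == "phm" else build_nhm
        return builder(t_modes, ref.modes, domain)
    if method == "chm":
        t_cdf = cumulative_distribution(compute_histogram(target))
        return build_chm(t_cdf, ref.brain_cdf, domain=domain)
    if method == "rls":
        gm_t, wm_t = _roi_medians(target, target_labels, target_spec)
        gm_r, wm_r = ref.roi_medians
        return build_rls(ROIMedians(gm_t, wm_t, gm_r, wm_r), domain)
    if method == "sps":
        stats = tissue_stats(target, target_labels)
        return build_sps(
            (stats.mean["CSF"], stats.mean["GM"], stats.mean["WM"]),
            ref.tissue_means, domain)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# The benchmark
# ---------------------------------------------------------------------------

def _region_cdfs(vol, labels, gm_roi, wm_roi):
    return {
        "whole_brain_GM": cumulative_distribution(
            compute_histogram(vol, labels=labels, tissue="GM")),
        "whole_brain_WM": cumulative_distribution(
            compute_histogram(vol, labels=labels, tissue="WM")),
        "GM_ROI": cumulative_distribution(compute_histogram(vol, mask=gm_roi)),
        "WM_ROI": cumulative_distribution(compute_histogram(vol, mask=wm_roi)),
    }


def run_benchmark(cfg: RunConfig) -> Path:
    """Run the full benchmark; returns the report directory."""
    issues = validate_config(cfg)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "transforms").mkdir(exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    sds = (
        {"CSF": 0.0, "GM": 0.0, "WM": 0.0}
        if cfg.noiseless else dict(DEFAULT_TISSUE_SDS)
    )
    ref_spec = PhantomSpec(
        grid_shape=tuple(cfg.grid_shape),
        hypothalamus_radius_vox=cfg.hypothalamus_radius_vox,
        wm_shell_radius_vox=cfg.wm_shell_radius_vox,
        tissue_sds=sds,
        intensity_min=cfg.intensity_min,
        intensity_max=cfg.intensity_max,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ref_vol, ref_true = generate_phantom(ref_spec)
    ref_ctx = make_reference_context(ref_vol, ref_spec)
    ref_gm_roi, ref_wm_roi = phantom_rois(ref_ctx.labels, ref_spec)

    subjects = generate_cohort(
        n_subjects=cfg.n_targets,
        seed=int(rng.integers(0, 2**31 - 1)),
        grid_shape=tuple(cfg.grid_shape),
        noiseless=cfg.noiseless,
        hypothalamus_radius_vox=cfg.hypothalamus_radius_vox,
        wm_shell_radius_vox=cfg.wm_shell_radius_vox,
    )

    # apply a known interscan distortion to each subject
    distortions, natives = [], []
    for s in subjects:
        if cfg.distortion_kind == "identity":
            d = DistortionSpec("identity")
        elif cfg.distortion_kind == "offset":
            d = DistortionSpec("offset", {"offset": float(rng.uniform(*cfg.offset_range))})
        elif cfg.distortion_kind == "study":
            d = sample_study_distortion(rng, cfg.gm_shift_range, cfg.wm_shift_range)
        else:
            d = DistortionSpec("linear", {
                "slope": float(rng.uniform(*cfg.slope_range)),
                "offset": float(rng.uniform(*cfg.offset_range)),
            })
        distortions.append(d)
        natives.append(apply_distortion(s.volume, d))

    native_ctx = []  # per-target: (labels, gm_roi, wm_roi, cdfs, boundary, stats)
    for s, nat in zip(subjects, natives):
        labels = _segment_labels(nat)
        gm_roi, wm_roi = phantom_rois(labels, s.spec)
        native_ctx.append({
            "labels": labels,
            "gm_roi": gm_roi,
            "wm_roi": wm_roi,
            "cdfs": _region_cdfs(nat, labels, gm_roi, wm_roi),
            "boundary": interface_boundary_intensity(nat, labels),
            "stats": tissue_stats(nat, labels),
        })

    hist_rows, vox_rows, boundary_rows, maint_rows = [], [], [], []
    ages = np.array([s.age for s in subjects])
    regions = ("whole_brain_GM", "whole_brain_WM", "GM_ROI", "WM_ROI")

    # native baselines (degenerate histograms with no shared range -> NaN)
    native_errors = {
        reg: {
            "avg": [_cdf_err(ctx["cdfs"][reg],
                             _ref_cdf(ref_ctx, ref_gm_roi, ref_wm_roi, reg))[0]
                    for ctx in native_ctx],
            "max": [_cdf_err(ctx["cdfs"][reg],
                             _ref_cdf(ref_ctx, ref_gm_roi, ref_wm_roi, reg))[1]
                    for ctx in native_ctx],
        }
        for reg in regions
    }
    native_vox = {
        key: [_voxdiff(ref_ctx, ctx, nat, key, ref_gm_roi, ref_wm_roi)
              for ctx, nat in zip(native_ctx, natives)]
        for key in ("GM_whole", "WM_whole", "GM_ROI", "WM_ROI")
    }
    native_boundary = np.array([ctx["boundary"] for ctx in native_ctx])
    native_gm_vol = np.array([ctx["stats"].volume_mm3["GM"] for ctx in native_ctx])

    for reg in regions:
        for metric in ("avg", "max"):
            hist_rows.append({
                "method": "native", "region": reg, "metric": metric,
                "median": float(np.median(native_errors[reg][metric])),
                "min": float(np.min(native_errors[reg][metric])),
                "max": float(np.max(native_errors[reg][metric])),
                "Z": np.nan, "p": np.nan, "r": np.nan,
            })
    for key, vals in native_vox.items():
        vox_rows.append({
            "method": "native", "region": key,
            "median": float(np.median(vals)),
            "min": float(np.min(vals)), "max": float(np.max(vals)),
            "Z": np.nan, "p": np.nan, "r": np.nan,
        })
    boundary_rows.append({
        "method": "native", "sd": float(np.std(native_boundary, ddof=1)),
        "t": np.nan, "df": np.nan, "p": np.nan,
    })

    for method in cfg.methods:
        method = method.lower()
        std_errors = {reg: {"avg": [], "max": []} for reg in regions}
        std_vox = {key: [] for key in native_vox}
        std_boundary, std_gm_vol = [], []
        for k, (s, nat, ctx) in enumerate(zip(subjects, natives, native_ctx)):
            try:
                t = build_method_transform(method, nat, ctx["labels"], s.spec, ref_ctx)
            except Exception as e:
                raise RuntimeError(
                    f"stage 'standardize/{method}' failed on target {k}: {e}"
                ) from e
            serialize_transform(t, out / "transforms" / f"{method}_target{k:02d}.json")
            std = apply_transform(nat, t)
            if cfg.quantize:
                std = std.copy_with(
                    np.clip(np.rint(std.data), cfg.intensity_min, cfg.intensity_max))
            std_labels = _segment_labels(std)
            gm_roi, wm_roi = phantom_rois(std_labels, s.spec)
            cdfs = _region_cdfs(std, std_labels, gm_roi, wm_roi)
            sctx = {"labels": std_labels, "gm_roi": gm_roi, "wm_roi": wm_roi}
            for reg in regions:
                avg, mx = _cdf_err(
                    cdfs[reg], _ref_cdf(ref_ctx, ref_gm_roi, ref_wm_roi, reg))
                std_errors[reg]["avg"].append(avg)
                std_errors[reg]["max"].append(mx)
            for key in std_vox:
                std_vox[key].append(
                    _voxdiff(ref_ctx, sctx, std, key, ref_gm_roi, ref_wm_roi))
            std_boundary.append(interface_boundary_intensity(std, std_labels))
            std_gm_vol.append(tissue_stats(std, std_labels).volume_mm3["GM"])
            if cfg.write_volumes:
                write_volume(std, out / f"{method}_target{k:02d}.nii.gz",
                             quantize=cfg.quantize)

        for reg in regions:
            for metric in ("avg", "max"):
                before = np.array(native_errors[reg][metric])
                after = np.array(std_errors[reg][metric])
                row = {
                    "method": method, "region": reg, "metric": metric,
                    "median": float(np.median(after)),
                    "min": float(np.min(after)), "max": float(np.max(after)),
                }
                row.update(_wilcoxon_row(before, after))
                hist_rows.append(row)
        for key in std_vox:
            before = np.array(native_vox[key])
            after = np.array(std_vox[key])
            row = {
                "method": method, "region": key,
                "median": float(np.median(after)),
                "min": float(np.min(after)), "max": float(np.max(after)),
            }
            row.update(_wilcoxon_row(before, after))
            vox_rows.append(row)
        try:
            pm = pitman_morgan(native_boundary, np.array(std_boundary))
            t_stat, t_df, t_p = pm.statistic, pm.df, pm.p_two_tailed
        except ValueError:  # zero residual variance: perfect standardisation
            t_stat, t_df, t_p = float("nan"), len(std_boundary) - 2, float("nan")
        boundary_rows.append({
            "method": method, "sd": float(np.std(std_boundary, ddof=1)),
            "t": t_stat, "df": t_df, "p": t_p,
        })
        maint = correlation_maintenance(native_gm_vol, np.array(std_gm_vol), ages)
        maint_rows.append({
            "method": method,
            "r_age_before": maint.r_age_before,
            "r_age_after": maint.r_age_after,
            "steiger_Z": maint.test.statistic,
            "p": maint.test.p_two_tailed,
            "cohens_q": maint.test.effect_size,
            "changed": maint.changed,
        })

    float_fmt = "%.10g"
    pd.DataFrame(hist_rows).to_csv(
        out / "histogram_comparison.csv", index=False, float_format=float_fmt)
    pd.DataFrame(vox_rows).to_csv(
        out / "intensity_difference.csv", index=False, float_format=float_fmt)
    pd.DataFrame(boundary_rows).to_csv(
        out / "boundary_intensity.csv", index=False, float_format=float_fmt)
    pd.DataFrame(maint_rows).to_csv(
        out / "maintenance.csv", index=False, float_format=float_fmt)

    cfg_dict = dataclasses.asdict(cfg)
    manifest = {
        "package": "mristand",
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "distortions": [
            {"kind": d.kind, "params": d.params} for d in distortions],
        "subject_ages": ages.tolist(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def cohort_correlation_experiment(
    method: str,
    n_subjects: int = 12,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (40, 40, 40),
    noiseless: bool = False,
) -> "object":
    """Maintenance-of-biological-variation experiment on one seeded cohort.

    Generates an age-linked cohort plus a reference phantom, applies
    interscan distortions, standardises every subject to the reference with
    ``method``, re-segments, and tests whether the age-GM-volume correlation
    survived (Steiger's Z).  Returns the :class:`CorrelationMaintenance`.
    """
    rng = np.random.default_rng(seed)
    sds = {"CSF": 0.0, "GM": 0.0, "WM": 0.0} if noiseless else None
    ref_spec = PhantomSpec(
        grid_shape=grid_shape, hypothalamus_radius_vox=5, wm_shell_radius_vox=7,
        tissue_sds=sds or dict(DEFAULT_TISSUE_SDS),
        seed=int(rng.integers(0, 2**31 - 1)))
    ref_vol, _ = generate_phantom(ref_spec)
    ref_ctx = make_reference_context(ref_vol, ref_spec)
    subjects = generate_cohort(
        n_subjects=n_subjects, seed=int(rng.integers(0, 2**31 - 1)),
        grid_shape=grid_shape, noiseless=noiseless,
        hypothalamus_radius_vox=5, wm_shell_radius_vox=7)
    ages, before, after = [], [], []
    for s in subjects:
        if noiseless:
            d = DistortionSpec("linear", {
                "slope": float(rng.uniform(0.9, 1.1)),
                "offset": float(rng.uniform(-100.0, 100.0))})
        else:
            d = sample_study_distortion(rng)
        nat = apply_distortion(s.volume, d)
        nat_labels = _segment_labels(nat)
        t = build_method_transform(method, nat, nat_labels, s.spec, ref_ctx)
        std = apply_transform(nat, t)
        std_labels = _segment_labels(std)
        ages.append(s.age)
        before.append(tissue_stats(nat, nat_labels).volume_mm3["GM"])
        after.append(tissue_stats(std, std_labels).volume_mm3["GM"])
    return correlation_maintenance(before, after, ages)


def _ref_cdf(ref_ctx, ref_gm_roi, ref_wm_roi, region):
    if not hasattr(ref_ctx, "_region_cdfs"):
        ref_ctx._region_cdfs = _region_cdfs(
            ref_ctx.volume, ref_ctx.labels, ref_gm_roi, ref_wm_roi)
    return ref_ctx._region_cdfs[region]


def _voxdiff(ref_ctx, ctx, vol, key, ref_gm_roi, ref_wm_roi):
    tissue = "GM" if key.startswith("GM") else "WM"
    roi = None
    if key.endswith("ROI"):
        roi = ref_gm_roi if tissue == "GM" else ref_wm_roi
    return voxelwise_intensity_difference(
        ref_ctx.volume, vol, ref_ctx.labels, ctx["labels"], tissue, roi=roi)


def _cdf_err(target, reference) -> tuple[float, float]:
    try:
        res = cdf_abs_error(target, reference)
        return res.average_abs_error, res.maximum_abs_error
    except ValueError:
        return float("nan"), float("nan")


def _wilcoxon_row(before: np.ndarray, after: np.ndarray) -> dict:
    keep = np.isfinite(before) & np.isfinite(after)
    try:
        res = wilcoxon_signed_rank(before[keep], after[keep])
        return {"Z": res.statistic, "p": res.p_two_tailed, "r": res.effect_size}
    except ValueError:
        return {"Z": 0.0, "p": 1.0, "r": 0.0}
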