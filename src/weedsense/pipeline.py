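"""Study orchestration: simulate a field study, process samples, run analyses.

A study directory holds, per sampling point, a *before* photograph (crop
plus weeds inside the frame), an *after* photograph (crop only, weeds
removed), and an ultrasonic voltage trace; plus a field table with the
hand-measured covariates and infestation labels, and a flat config file.

``process_sample`` runs the imaging chain on both photographs and the
sensor chain on the trace; weed coverage is the before-minus-after
coverage difference, floored at zero because segmentation noise can make
the after image score marginally higher.  ``run_study`` loops over all
samples (per-sample failures are recorded, never fatal), then emits the
correlation table, the multiple-regression report and the binary and
four-group canonical-discriminant confusion matrices as files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, sensor, stats, synthetic
from .imaging import HsvThresholds
from .sensor import CalibrationModel, SensorConfig
from .synthetic import FieldSimConfig

__all__ = [
    "StudyConfig",
    "SampleResult",
    "StudyReport",
    "process_sample",
    "run_study",
    "simulate",
    "save_config",
    "load_config",
]

log = logging.getLogger("weedsense")

#: Continuous covariates correlated/regressed against the measured height.
COVARIATES = [
    "weed_coverage", "grass_height", "bl_height", "crop_height",
    "grass_density", "bl_density", "crop_density",
    "grass_biomass", "bl_biomass", "crop_biomass",
]


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of a study run; defaults are the standard chain parameters."""

    radius_range: tuple[int, int] = (100, 140)
    exg_fraction: float = 0.08
    median_size: int = 10
    roi_shrink: int = 10
    hsv: HsvThresholds = field(default_factory=HsvThresholds)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    calibration: CalibrationModel = field(default_factory=CalibrationModel)
    alpha_drop: float = 0.10
    priors: str = "equal"
    cda_features: tuple[str, ...] = ("ultrasonic_height",)
    seed: int = 0


@dataclass(frozen=True)
class SampleResult:
    """Measured quantities for one sampling point."""

    sample_id: str
    status: str  # "ok" or a machine-readable failure reason
    height_cm: float = float("nan")
    n_invalid: int = 0
    coverage_before: float = float("nan")
    coverage_after: float = float("nan")
    weed_coverage: float = float("nan")
    roi_before: imaging.ROICircle | None = None
    roi_after: imaging.ROICircle | None = None


@dataclass(frozen=True)
class StudyReport:
    samples: pd.DataFrame
    correlations: pd.DataFrame | None
    regression: stats.RegressionResult | None
    cda_binary: stats.ConfusionMatrix | None
    cda_four: stats.ConfusionMatrix | None
    skipped: dict


def process_sample(sample_id: str, before_rgb: np.ndarray, after_rgb: np.ndarray,
                   trace_volts: np.ndarray, cfg: StudyConfig = StudyConfig()) -> SampleResult:
    """Run imaging on the before/after pair and the sensor chain on the trace.

    Failure of any stage yields a SampleResult whose ``status`` carries a
    machine-readable reason (``roi_not_found``, ``no_valid_readings``)
    instead of raising, so study runs continue past bad samples.
    """
    try:
        before = imaging.measure_plot(before_rgb, cfg.radius_range, thr=cfg.hsv,
                                      median_size=cfg.median_size, shrink=cfg.roi_shrink,
                                      exg_fraction=cfg.exg_fraction)
        after = imaging.measure_plot(after_rgb, cfg.radius_range, thr=cfg.hsv,
                                     median_size=cfg.median_size, shrink=cfg.roi_shrink,
                                     exg_fraction=cfg.exg_fraction)
    except ValueError:
        log.warning("sample %s: ROI not found", sample_id)
        return SampleResult(sample_id=sample_id, status="roi_not_found")
    try:
        summary = sensor.summarize_sample(trace_volts, cfg=cfg.sensor, calib=cfg.calibration)
    except ValueError:
        log.warning("sample %s: no valid sensor readings", sample_id)
        return SampleResult(sample_id=sample_id, status="no_valid_readings",
                            coverage_before=before.result.coverage,
                            coverage_after=after.result.coverage,
                            roi_before=before.roi, roi_after=after.roi)
    c_before = before.result.coverage
    c_after = after.result.coverage
    return SampleResult(
        sample_id=sample_id, status="ok",
        height_cm=summary.mean_height_cm, n_invalid=summary.n_invalid,
        coverage_before=c_before, coverage_after=c_after,
        weed_coverage=max(c_before - c_after, 0.0),
        roi_before=before.roi, roi_after=after.roi)


# ---------------------------------------------------------------------------
# Study directory layout helpers

def _paths(study_dir: Path, sid: str) -> tuple[Path, Path, Path]:
    return (study_dir / "images" / f"{sid}_before.png",
            study_dir / "images" / f"{sid}_after.png",
            study_dir / "traces" / f"{sid}.csv")


def run_study(study_dir, out_dir, cfg: StudyConfig | None = None) -> StudyReport:
    """Process every sample in a study directory and write the analysis files.

    Outputs (CSV/JSON under ``out_dir``): ``samples.csv``,
    ``correlations.csv``, ``regression.csv`` + ``regression.json``,
    ``cda_binary_confusion.csv``, ``cda_four_confusion.csv``,
    ``report.json``.  Analyses that cannot run (too few valid samples,
    fewer than two groups) are skipped with an explicit reason in the
    report.  The run is deterministic: identical inputs give byte-identical
    outputs.
    """
    study_dir = Path(study_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg is None:
        cfg_path = study_dir / "config.yaml"
        cfg = load_config(cfg_path) if cfg_path.exists() else StudyConfig()
    field_table = pd.read_csv(study_dir / "field.csv")

    results = []
    for sid in field_table["sample_id"]:
        p_before, p_after, p_trace = _paths(study_dir, sid)
        if not (p_before.exists() and p_after.exists() and p_trace.exists()):
            results.append(SampleResult(sample_id=sid, status="missing_files"))
            continue
        res = process_sample(sid, imaging.read_image(p_before), imaging.read_image(p_after),
                             sensor.read_trace(p_trace)["volts"].to_numpy(), cfg)
        results.append(res)

    samples = pd.DataFrame([{
        "sample_id": r.sample_id, "status": r.status, "ultrasonic_height": r.height_cm,
        "n_invalid": r.n_invalid, "coverage_before": r.coverage_before,
        "coverage_after": r.coverage_after, "weed_coverage": r.weed_coverage,
        "roi_x0": r.roi_before.x0 if r.roi_before else np.nan,
        "roi_y0": r.roi_before.y0 if r.roi_before else np.nan,
        "roi_r": r.roi_before.r if r.roi_before else np.nan,
    } for r in results])
    samples.to_csv(out_dir / "samples.csv", index=False, float_format="%.10g")

    # merge measured quantities with the hand-measured covariates
    measured = samples[samples["status"] == "ok"][
        ["sample_id", "ultrasonic_height", "weed_coverage", "coverage_after"]]
    merged = measured.merge(
        field_table.drop(columns=["ultrasonic_height", "weed_coverage"], errors="ignore"),
        on="sample_id")

    skipped: dict[str, str] = {}
    correlations = regression = cda_binary = cda_four = None

    if len(merged) < 3:
        skipped["correlations"] = skipped["regression"] = "fewer_than_3_valid_samples"
        skipped["cda"] = "fewer_than_3_valid_samples"
    else:
        rows = {}
        for var in COVARIATES:
            if var not in merged.columns:
                continue
            try:
                pr = stats.pearson(merged[var], merged["ultrasonic_height"])
                rows[var] = {"r": pr.r, "r_squared": pr.r_squared, "p_value": pr.p_value}
            except ValueError as e:
                rows[var] = {"r": np.nan, "r_squared": np.nan, "p_value": np.nan}
                log.info("correlation for %s skipped: %s", var, e)
        correlations = pd.DataFrame.from_dict(rows, orient="index",
                                              columns=["r", "r_squared", "p_value"])
        correlations.to_csv(out_dir / "correlations.csv", index_label="variable",
                            float_format="%.10g")

        predictors = [v for v in COVARIATES if v in merged.columns
                      and merged[v].std() > 0]
        try:
            regression = stats.multiple_regression(merged, "ultrasonic_height",
                                                   predictors, alpha_drop=cfg.alpha_drop)
            regression.table.to_csv(out_dir / "regression.csv", index_label="predictor",
                                    float_format="%.10g")
            (out_dir / "regression.json").write_text(json.dumps({
                "intercept": regression.intercept, "excluded": regression.excluded,
                "r_squared": regression.r_squared,
                "adj_r_squared": regression.adj_r_squared, "nobs": regression.nobs,
            }, indent=2, sort_keys=True) + "\n")
        except ValueError as e:
            skipped["regression"] = str(e)

        for name, label in (("cda_binary", "weed_presence"), ("cda_four", "infestation")):
            try:
                model = stats.cda_fit(merged, label, list(cfg.cda_features),
                                      priors=cfg.priors)
                pred = stats.cda_classify(model, merged)
                cm = stats.confusion_percentages(merged[label], pred, labels=model.labels)
                cm.percentages.to_csv(out_dir / f"{name}_confusion.csv",
                                      index_label="true_group", float_format="%.10g")
                if name == "cda_binary":
                    cda_binary = cm
                else:
                    cda_four = cm
            except ValueError as e:
                skipped[name] = str(e)
                log.info("%s skipped: %s", name, e)

    report = {
        "n_samples": int(len(samples)),
        "n_valid": int((samples["status"] == "ok").sum()),
        "status_counts": samples["status"].value_counts().to_dict(),
        "skipped": skipped,
        "cda_binary_accuracy": cda_binary.accuracy if cda_binary else None,
        "cda_four_accuracy": cda_four.accuracy if cda_four else None,
        "regression_adj_r_squared": regression.adj_r_squared if regression else None,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return StudyReport(samples=samples, correlations=correlations, regression=regression,
                       cda_binary=cda_binary, cda_four=cda_four, skipped=skipped)


# ---------------------------------------------------------------------------
# Study simulation

def simulate(out_dir, n_per_group: int | dict | None = None, seed: int = 0,
             image_size: int = 320, radius: int = 110, frame_width: int = 12,
             crop_coverage_moments: tuple[float, float] = (0.25, 0.08),
             trace_len: int = 30, voltage_noise_sd: float = 0.02,
             field_cfg: FieldSimConfig | None = None) -> StudyConfig:
    """Build a complete synthetic study directory with ground truth.

    Per sample: a before image painted at crop + weed coverage, an after
    image at crop coverage only (both sharing the frame geometry), and a
    voltage trace whose true distance is the mounting reference minus the
    sample's ultrasonic height.  Writes ``field.csv``, ``truth.json`` and
    ``config.yaml``; returns the StudyConfig that was written.

    The frame radius is constant across samples (one frame, one camera
    height) and the written config searches radius +/- 2 px only: inside a
    filled annulus every smaller radius collects a full circle of votes, so
    a wide radius scan is ill-posed and the frame size is treated as known
    geometry, as in a fixed-radius deployment.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    if field_cfg is None:
        field_cfg = FieldSimConfig(n_per_group=n_per_group, seed=int(rng.integers(2**31)))
    table = synthetic.gen_field_table(field_cfg)
    table.to_csv(out_dir / "field.csv", index=False, float_format="%.10g")

    scfg = StudyConfig(radius_range=(radius - 2, radius + 2), seed=seed)
    truths = {}
    half = image_size // 2
    for _, row in table.iterrows():
        sid = row["sample_id"]
        cx = half + int(rng.integers(-6, 7))
        cy = half + int(rng.integers(-6, 7))
        r = radius
        crop_cov = float(synthetic._draw_truncated(rng, *crop_coverage_moments, 1)[0])
        weed_cov = float(row["weed_coverage"])
        img_b, img_a, pair = synthetic.gen_plot_pair(
            center=(cx, cy), radius=r, crop_coverage=crop_cov, weed_coverage=weed_cov,
            seed=int(rng.integers(2**31)), size=(image_size, image_size),
            frame_width=frame_width)
        p_before, p_after, p_trace = _paths(out_dir, sid)
        imaging.write_image(p_before, img_b)
        imaging.write_image(p_after, img_a)
        dist = scfg.sensor.reference_distance_cm - float(row["ultrasonic_height"])
        trace = synthetic.gen_voltage_trace(np.full(trace_len, dist),
                                            noise_sd=voltage_noise_sd,
                                            seed=int(rng.integers(2**31)),
                                            calib=scfg.calibration, cfg=scfg.sensor)
        trace.to_csv(p_trace, index=False, float_format="%.10g")
        truths[sid] = {"before": dataclasses.asdict(pair.before),
                       "after": dataclasses.asdict(pair.after),
                       "weed_fraction": pair.weed_fraction,
                       "true_distance_cm": dist}
    (out_dir / "truth.json").write_text(json.dumps(truths, indent=2, sort_keys=True) + "\n")
    save_config(scfg, out_dir / "config.yaml")
    return scfg


# ---------------------------------------------------------------------------
# Flat config file (dotted keys, YAML syntax)

def save_config(cfg: StudyConfig, path) -> None:
    flat = {
        "imaging.radius_min": cfg.radius_range[0],
        "imaging.radius_max": cfg.radius_range[1],
        "imaging.exg_fraction": cfg.exg_fraction,
        "imaging.median_size": cfg.median_size,
        "imaging.roi_shrink": cfg.roi_shrink,
        "imaging.hsv_h": list(cfg.hsv.h),
        "imaging.hsv_s": list(cfg.hsv.s),
        "imaging.hsv_v": list(cfg.hsv.v),
        "sensor.reference_distance_cm": cfg.sensor.reference_distance_cm,
        "sensor.range_min_mm": cfg.sensor.range_min_mm,
        "sensor.range_max_mm": cfg.sensor.range_max_mm,
        "sensor.error_sentinel_volts": cfg.sensor.error_sentinel_volts,
        "calibration.slope": cfg.calibration.slope,
        "calibration.intercept": cfg.calibration.intercept,
        "calibration.r_squared": cfg.calibration.r_squared,
        "stats.alpha_drop": cfg.alpha_drop,
        "stats.priors": cfg.priors,
        "stats.cda_features": list(cfg.cda_features),
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=True))


def load_config(path) -> StudyConfig:
    flat = yaml.safe_load(Path(path).read_text())
    return StudyConfig(
        radius_range=(int(flat["imaging.radius_min"]), int(flat["imaging.radius_max"])),
        exg_fraction=float(flat["imaging.exg_fraction"]),
        median_size=int(flat["imaging.median_size"]),
        roi_shrink=int(flat["imaging.roi_shrink"]),
        hsv=HsvThresholds(h=tuple(flat["imaging.hsv_h"]), s=tuple(flat["imaging.hsv_s"]),
                          v=tuple(flat["imaging.hsv_v"])),
        sensor=SensorConfig(
            reference_distance_cm=float(flat["sensor.reference_distance_cm"]),
            range_min_mm=float(flat["sensor.range_min_mm"]),
            range_max_mm=float(flat["sensor.range_max_mm"]),
            error_sentinel_volts=float(flat["sensor.error_sentinel_volts"])),
        calibration=CalibrationModel(slope=float(flat["calibration.slope"]),
                                     intercept=float(flat["calibration.intercept"]),
                                     r_squared=float(flat["calibration.r_squared"])),
        alpha_drop=float(flat["stats.alpha_drop"]),
        priors=str(flat["stats.priors"]),
        cda_features=tuple(flat["stats.cda_features"]),
        seed=int(flat["seed"]),
    )
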