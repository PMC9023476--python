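"""End-to-end orchestration: video -> haemodynamics -> cohort -> screening.

``extract_haemodynamics`` runs one video through registration, vessel
segmentation, EDT diameters and wavelet velocimetry.  ``run_pipeline``
drives a full synthetic study: a handful of ground-truthed videos to
validate the imaging chain, a simulated case-control cohort, the LOD /
log10 preparation, group comparisons, and the stepwise screening model
with its ranked diagnostic-accuracy report.  Every output is a CSV or
JSON in the run directory; a manifest records config, seed and versions
so a rerun reproduces every table bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import (DEFAULT_LOG10_VARIABLES, apply_log10,
                         aggregate_patient, impute_table)
from .config import PipelineConfig
from .frames import FrameStack
from .geometry import (edt_diameter, extract_centerlines, include_segment,
                       score_quality, segment_vessels, segments_to_csv)
from .registration import register_frames
from .screening import (StepwiseLogisticScreener, compare_groups,
                        format_report, model_comparison_report)
from .synthetic import (CohortSimConfig, VideoSimConfig, render_vessel_video,
                        simulate_cohort)
from .tables import CohortTable
from .velocimetry import (SegmentHaemodynamics, VelocimetryConfig, build_sti,
                          estimate_axial_velocity_cwt)

__all__ = ["extract_haemodynamics", "run_pipeline", "haemodynamics_to_csv"]

log = logging.getLogger("ocuflow")


def extract_haemodynamics(stack: FrameStack,
                          config: PipelineConfig | None = None
                          ) -> list[SegmentHaemodynamics]:
    """Per-segment haemodynamics for one video.

    Registers the stack to its sharpest frame, segments vessels on the
    reference frame, keeps centreline segments passing the quality gate,
    and estimates D (EDT), Va (wavelet STI), Vs, Q and WSR per segment.
    Segments with indeterminate velocity are dropped.
    """
    cfg = config or PipelineConfig()
    reg = register_frames(stack)
    ref_frame = reg.registered.frames[reg.reference_index]
    vmask = segment_vessels(ref_frame, stack.um_per_px)
    segments = extract_centerlines(vmask, min_spur_px=cfg.geometry.min_spur_px)
    vel_cfg = VelocimetryConfig(k_axial_to_cross=cfg.k_axial_to_cross,
                                wavelet_scales_um=cfg.wavelet_scales_um,
                                min_streak_snr=cfg.min_streak_snr)
    out: list[SegmentHaemodynamics] = []
    for seg in segments:
        seg.quality = score_quality(ref_frame, seg,
                                    contrast_floor=cfg.geometry.contrast_floor)
        if not include_segment(seg, cfg.geometry.quality_floor,
                               cfg.geometry.min_length_um):
            continue
        seg = edt_diameter(vmask, seg)
        try:
            sti = build_sti(reg.registered, seg)
        except ValueError:
            continue
        va = estimate_axial_velocity_cwt(sti, vel_cfg)
        if va is None:
            continue
        out.append(SegmentHaemodynamics.from_measurements(
            seg.mean_diameter_um, va, vel_cfg, segment_id=seg.segment_id))
    return out


def haemodynamics_to_csv(haemo: list[SegmentHaemodynamics], path) -> None:
    pd.DataFrame([{
        "segment_id": h.segment_id, "D_um": h.diameter_um,
        "Va_mm_s": h.axial_velocity_mm_s, "Vs_mm_s": h.cross_velocity_mm_s,
        "Q_pl_s": h.flow_pl_s, "WSR_per_s": h.wsr_per_s,
    } for h in haemo]).to_csv(path, index=False)


@dataclass
class _StageTimer:
    manifest: dict

    def record(self, stage: str, t0: float, **counts) -> None:
        self.manifest.setdefault("stages", {})[stage] = {
            "wall_s": round(time.perf_counter() - t0, 3), **counts}
        log.info("stage %s done in %.2fs %s", stage,
                 time.perf_counter() - t0, counts or "")


def run_pipeline(out_dir: str | Path,
                 config: PipelineConfig | None = None,
                 n_videos: int = 3,
                 video_truths: list[tuple[float, float]] | None = None,
                 cohort: CohortTable | None = None,
                 cohort_csv: str | Path | None = None,
                 n_control: int = 66, n_case: int = 66,
                 video_frames: int = 100) -> Path:
    """Run the full synthetic study into ``out_dir`` and return its path.

    ``video_truths`` lists (diameter_um, va_mm_s) ground truths for the
    validation videos; the cohort is simulated at the published group
    moments unless one is supplied.  Any stage failure halts the run with
    the stage name; partial outputs are retained.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "seed": cfg.seed,
                      "ocuflow_version": __version__}
    timer = _StageTimer(manifest)
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(8)]

    try:
        # ---------------------------------------------- stage 1: videos
        t0 = time.perf_counter()
        truths = video_truths or [(16.0, 0.3), (22.0, 0.5), (30.0, 0.7)]
        truths = truths[:n_videos] if n_videos <= len(truths) else truths
        video_rows = []
        for i, (d_true, va_true) in enumerate(truths):
            vcfg = VideoSimConfig(
                n_frames=video_frames, fps=cfg.fps, um_per_px=cfg.um_per_px,
                vessel_diameter_um=d_true, axial_velocity_mm_s=va_true,
                seed=child_seeds[0] + i)
            stack, truth = render_vessel_video(vcfg)
            stack.to_tiff(out / f"video_{i}.tiff")
            truth.to_json(out / f"video_{i}.truth.json")
            haemo = extract_haemodynamics(stack, cfg)
            haemodynamics_to_csv(haemo, out / f"video_{i}.haemodynamics.csv")
            pooled = aggregate_patient({"v": haemo})
            video_rows.append({
                "video": i, "D_true_um": d_true, "Va_true_mm_s": va_true,
                "n_segments": len(haemo),
                "D_est_um": pooled["diameter"] if pooled else np.nan,
                "Va_est_mm_s": pooled["va"] if pooled else np.nan,
            })
        vdf = pd.DataFrame(video_rows)
        vdf.to_csv(out / "video_validation.csv", index=False)
        timer.record("videos", t0, n_videos=len(truths))

        # ---------------------------------------------- stage 2: cohort
        t0 = time.perf_counter()
        if cohort is None:
            if cohort_csv is not None:
                cohort = CohortTable.from_csv(cohort_csv)
            else:
                cohort = simulate_cohort(CohortSimConfig(
                    n_control=n_control, n_case=n_case, seed=child_seeds[1]))
        cohort.to_csv(out / "cohort_raw.csv")
        timer.record("cohort", t0, n_subjects=len(cohort.data))

        # ---------------------------------------------- stage 3: prep
        t0 = time.perf_counter()
        prepped = impute_table(cohort)
        log_vars = [v for v in DEFAULT_LOG10_VARIABLES
                    if v in prepped.data.columns]
        prepped = apply_log10(prepped, log_vars)
        prepped.to_csv(out / "cohort_prepped.csv")
        timer.record("prep", t0, log10_vars=len(log_vars))

        # ---------------------------------------------- stage 4: compare
        t0 = time.perf_counter()
        comp_rows = []
        for name, meta in prepped.variables.items():
            if name not in prepped.data.columns:
                continue
            try:
                res = compare_groups(prepped, name)
            except ValueError:
                continue
            comp_rows.append({
                "variable": meta.display_name, "test": res.test_name,
                "statistic": res.statistic, "p_value": res.p_value,
                **{f"summary_{g}": s for g, s in res.group_summaries.items()}})
        pd.DataFrame(comp_rows).to_csv(out / "group_comparisons.csv",
                                       index=False)
        timer.record("compare", t0, n_variables=len(comp_rows))

        # ---------------------------------------------- stage 5: screen
        t0 = time.perf_counter()
        candidates = [v for v in
                      ("nt_probnp", "adiponectin", "vs", "h_fabp", "va",
                       "wsr", "il6", "crp", "diameter")
                      if v in prepped.data.columns]
        X = prepped.data[candidates]
        y = (prepped.data["group"] == "post-MI").astype(int)
        screener = StepwiseLogisticScreener(
            p_enter=cfg.stats.p_enter, p_remove=cfg.stats.p_remove,
            classification_cut=cfg.stats.classification_cut,
            hosmer_lemeshow_groups=cfg.stats.hosmer_lemeshow_groups)
        screener.fit(X, y)
        model = screener.model_
        screen = {
            "selected_variables": screener.variables_,
            "coefficients": model.coefficients.tolist(),
            "standard_errors": model.standard_errors.tolist(),
            "model_chi2": model.model_chi2, "model_df": model.model_df,
            "model_p": model.model_p,
            "nagelkerke_r2": screener.nagelkerke_r2_,
            "hosmer_lemeshow": (
                {"chi2": screener.hosmer_lemeshow_.chi2,
                 "df": screener.hosmer_lemeshow_.df,
                 "p": screener.hosmer_lemeshow_.p_value}
                if screener.hosmer_lemeshow_ else None),
            "trace": [vars(r) for r in screener.trace_.records],
        }
        if screener.roc_ is not None:
            op = screener.roc_.operating_point
            screen["auroc"] = screener.roc_.auroc
            screen["operating_point"] = op
            pd.DataFrame({
                "threshold": screener.roc_.thresholds,
                "sensitivity": screener.roc_.sensitivity,
                "specificity": screener.roc_.specificity,
            }).to_csv(out / "roc_points.csv", index=False)
        (out / "screening_model.json").write_text(json.dumps(screen, indent=2))

        specs = [s for s in (
            ["nt_probnp", "adiponectin", "vs"],
            ["nt_probnp", "adiponectin", "va"],
            ["h_fabp", "nt_probnp", "vs"],
            ["nt_probnp", "vs"],
            ["il6", "vs"],
            ["nt_probnp"],
            ["vs"],
            ["adiponectin"],
        ) if all(v in prepped.data.columns for v in s)]
        report = model_comparison_report(
            prepped, specs, classification_cut=cfg.stats.classification_cut)
        report.drop(columns=["variables"]).to_csv(
            out / "model_comparison.csv", index=False)
        (out / "model_comparison.txt").write_text(format_report(report))
        timer.record("screen", t0, n_models=len(specs))
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", "see traceback")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
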