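"""End-to-end pipeline: electrograms -> APDR -> GA -> clustering -> scans.

Reproduces the study workflow at a chosen scale.  Every stochastic stage
receives a seed derived deterministically from the global seed and the
stage name, so stages are independently reproducible and re-seeding one
stage leaves the others untouched.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as rio
from .ari import compare_cohorts, fit_cohort_curves
from .cell import alternans_scan, steady_biomarkers
from .clustering import PopulationClustering
from .egm import CohortSpec, NoiseSpec, synth_cohort
from .ga import GACalibrator
from .tissue import SCALED_CIS, SCALED_SIGMAS, TissueConfig, inducibility_sweep

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

COHORTS = ("snlv", "icmp")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (int(global_seed) * 1_000_033 + h) % (2**31 - 1)


@dataclass
class RunConfig:
    """Pipeline settings."""

    seed: int = 1
    outdir: str = "pipeline_out"
    stages: tuple = ("egm", "apdr", "ga", "cluster", "alternans", "tissue")
    ga_scale: str = "desk"  # desk | full
    tissue_scale: str = "scaled"  # scaled | full
    n_patients: int = 6
    electrodes_per_patient: int = 4
    ga_population: int = 100
    ga_generations: int = 60


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; returns (and writes) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "artifacts": {}}

    def record(stage, t0, **info):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 2), **info}

    curves = None
    ga_results = {}

    if "egm" in config.stages or "apdr" in config.stages:
        t0 = time.time()
        recordings = {}
        for cohort in COHORTS:
            spec = CohortSpec.from_cohort(cohort)
            recs = synth_cohort(
                spec,
                config.n_patients,
                config.electrodes_per_patient,
                noise=NoiseSpec(white_sd=0.02),
                rng_seed=derive_seed(config.seed, f"egm-{cohort}"),
            )
            recordings[cohort] = recs
            for rec in recs:
                rio.save_recording(rec, out / "egm" / cohort / rec.patient)
        record("egm", t0, patients_per_cohort=config.n_patients)

    if "apdr" in config.stages:
        t0 = time.time()
        frames = []
        for cohort in COHORTS:
            frames.append(fit_cohort_curves(recordings[cohort], cohort=cohort))
        import pandas as pd

        curves = pd.concat(frames, ignore_index=True)
        curves = curves[curves["accepted"]]
        curves.to_csv(out / "apdr_curves.csv", index=False)
        contrast = compare_cohorts(
            curves, seed=derive_seed(config.seed, "bootstrap"), n_boot=1000
        )
        (out / "cohort_contrast.json").write_text(json.dumps(contrast, indent=1))
        record("apdr", t0, n_curves=int(len(curves)), slope_diff=contrast["estimate"])

    if "ga" in config.stages:
        for cohort in COHORTS:
            t0 = time.time()
            pop = 1512 if config.ga_scale == "full" else config.ga_population
            gens = 300 if config.ga_scale == "full" else config.ga_generations
            cal = GACalibrator(
                seed=derive_seed(config.seed, f"ga-{cohort}"),
                population_size=pop,
                max_generations=gens,
            ).fit(cohort)
            ga_results[cohort] = cal
            rio.save_population(cal.result_, out / f"ga_{cohort}")
            record(
                f"ga-{cohort}",
                t0,
                best_fitness_ms=cal.best_fitness_,
                generations=cal.n_generations_,
                apd90_at_500=steady_biomarkers(cal.best_params_).APD90,
            )

    cluster_info = {}
    if "cluster" in config.stages and ga_results:
        t0 = time.time()
        for cohort, cal in ga_results.items():
            pc = PopulationClustering(k=4).fit(cal.population_)
            cluster_info[cohort] = pc
            summary = {
                "cophenetic": pc.cophenetic_,
                "sizes_top4": pc.cluster_sizes_.tolist(),
            }
            (out / f"cluster_{cohort}.json").write_text(json.dumps(summary, indent=1))
        record("cluster", t0)

    if "alternans" in config.stages and ga_results:
        t0 = time.time()
        onsets = {}
        for cohort, cal in ga_results.items():
            scan = alternans_scan(cal.best_params_)
            onsets[cohort] = scan.onset_cl
        (out / "alternans_onsets.json").write_text(json.dumps(onsets, indent=1))
        ordered = (
            onsets.get("icmp") is not None
            and (onsets.get("snlv") is None or onsets["icmp"] > onsets["snlv"])
        )
        record("alternans", t0, onsets=onsets, icmp_later_than_snlv=bool(ordered))

    if "tissue" in config.stages and ga_results:
        t0 = time.time()
        cfg = TissueConfig()
        windows = {}
        for cohort, cal in ga_results.items():
            if config.tissue_scale == "full":
                m = inducibility_sweep(
                    cal.best_params_,
                    sigmas=np.round(np.arange(0.001, 0.01201, 0.0005), 4),
                    cis=np.arange(500.0, 49.0, -5.0),
                    cfg=cfg,
                )
            else:
                m = inducibility_sweep(cal.best_params_, cfg=cfg)
            windows[cohort] = {
                str(sg): m.ci_window(i) for i, sg in enumerate(m.sigmas)
            }
        (out / "reentry_windows.json").write_text(json.dumps(windows, indent=1))
        record("tissue", t0, windows=windows)

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.suffix in (".csv", ".json"):
            manifest["artifacts"][str(f.relative_to(out))] = rio.file_checksum(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
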