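"""Readers, writers and schema validation for pipeline artifacts.

All tabular artifacts are CSV with headers; metadata is JSON.  Parameter
sets serialize as 28-key JSON maps (canonical order documented in
:data:`restforge.params.PARAM_NAMES`) or flat CSV rows.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .egm import EGMRecording
from .params import BOFCParams, PARAM_NAMES

__all__ = [
    "save_params_csv",
    "load_params_csv",
    "save_trace_csv",
    "save_recording",
    "load_recording",
    "save_population",
    "load_population",
    "file_checksum",
    "validate_files",
]


def save_params_csv(params: BOFCParams, path) -> None:
    pd.DataFrame([params.to_dict()], columns=list(PARAM_NAMES)).to_csv(path, index=False)


def load_params_csv(path) -> BOFCParams:
    df = pd.read_csv(path)
    missing = [n for n in PARAM_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing parameter column(s): {', '.join(missing)}")
    return BOFCParams.from_dict({n: float(df[n].iloc[0]) for n in PARAM_NAMES})


def save_trace_csv(trace, path, sidecar: bool = True) -> None:
    """Voltage trace as (time_ms, V_mV) CSV with a JSON sidecar."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    if sidecar:
        meta = {
            "dt_ms": trace.dt,
            "cl_ms": trace.cl,
            "stim_times_ms": np.asarray(trace.stim_times).tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def save_recording(rec: EGMRecording, outdir) -> None:
    """EGM container: per-channel sample CSVs plus a JSON sidecar.

    Layout: ``<outdir>/channel_<k>.csv`` (sample_index, mV), ``meta.json``
    (fs, bursts, stimulus times), ``truth.csv`` when ground truth exists.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch in range(rec.n_channels):
        pd.DataFrame(
            {"sample": np.arange(rec.samples.shape[1]), "mV": rec.samples[ch]}
        ).to_csv(outdir / f"channel_{ch:02d}.csv", index=False)
    meta = {
        "fs_hz": rec.fs,
        "patient": rec.patient,
        "n_channels": rec.n_channels,
        "bursts": [
            {"cl_ms": cl, "stim_times_ms": np.asarray(st).tolist()} for cl, st in rec.bursts
        ],
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    if rec.truth is not None:
        rec.truth.to_csv(outdir / "truth.csv", index=False)


def load_recording(outdir) -> EGMRecording:
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    chans = sorted(outdir.glob("channel_*.csv"))
    if len(chans) != meta["n_channels"]:
        raise ValueError(f"{outdir}: expected {meta['n_channels']} channel files, found {len(chans)}")
    samples = np.vstack([pd.read_csv(f)["mV"].to_numpy() for f in chans])
    truth_path = outdir / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    bursts = [(b["cl_ms"], np.asarray(b["stim_times_ms"], dtype=float)) for b in meta["bursts"]]
    return EGMRecording(
        fs=meta["fs_hz"], samples=samples, bursts=bursts, truth=truth, patient=meta["patient"]
    )


def save_population(result, outdir) -> None:
    """GA result bundle: population/fitness/history CSVs + config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = pd.DataFrame(result.population, columns=list(PARAM_NAMES))
    pop["fitness_ms"] = result.fitness
    pop.to_csv(outdir / "population.csv", index=False)
    pd.DataFrame({"generation": np.arange(1, len(result.history) + 1),
                  "best_fitness_ms": result.history}).to_csv(outdir / "history.csv", index=False)
    cfg = result.config
    echo = {
        "seed": cfg.seed,
        "population_size": cfg.population_size,
        "max_generations": cfg.max_generations,
        "generations_run": result.generations,
        "best_fitness_ms": result.best_fitness,
        "target": result.target_label,
        "protocol_cls": list(cfg.protocol.cls),
        "protocol_beats_per_cl": cfg.protocol.beats_per_cl,
    }
    (outdir / "config.json").write_text(json.dumps(echo, indent=1))
    result.best_params.to_json(outdir / "best_params.json")


def load_population(outdir):
    outdir = Path(outdir)
    pop = pd.read_csv(outdir / "population.csv")
    fitness = pop.pop("fitness_ms").to_numpy()
    return pop[list(PARAM_NAMES)].to_numpy(), fitness, BOFCParams.from_json(
        outdir / "best_params.json"
    )


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _validate_one(path: Path) -> list[str]:
    errors = []
    try:
        if path.suffix == ".json":
            data = json.loads(path.read_text())
            if path.name == "best_params.json" or set(data) >= set(PARAM_NAMES[:4]):
                missing = [n for n in PARAM_NAMES if n not in data]
                if path.name.endswith("params.json") and missing:
                    errors.append(f"{path}: missing parameter key(s): {', '.join(missing)}")
        elif path.suffix == ".csv":
            df = pd.read_csv(path)
            if df.empty:
                errors.append(f"{path}: empty table")
            if path.name == "population.csv":
                missing = [n for n in PARAM_NAMES if n not in df.columns]
                if missing:
                    errors.append(f"{path}: missing column(s): {', '.join(missing)}")
    except Exception as exc:  # malformed file: report, do not raise
        msg = str(exc)
        errors.append(f"{path}: {type(exc).__name__}: {msg}")
    return errors


def validate_files(path) -> dict:
    """Schema validation of all CSV/JSON artifacts under ``path``.

    Returns {'checked': n, 'errors': [messages]}; a missing path is an
    error.
    """
    root = Path(path)
    if not root.exists():
        return {"checked": 0, "errors": [f"{path}: does not exist"]}
    files = [root] if root.is_file() else sorted(
        f for f in root.rglob("*") if f.suffix in (".csv", ".json")
    )
    errors = []
    for f in files:
        errors.extend(_validate_one(f))
    return {"checked": len(files), "errors": errors}
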