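"""End-to-end run orchestration: simulate -> preprocess -> train -> predict -> stats.

A run directory is created under ``<out>/<run_id>`` with the merged config
snapshot, a log file, and one subdirectory per stage output:

* ``data/``        internal-format recordings + ``ages.csv`` (simulate)
* ``graphs/``      per-recording float32 spectrogram stacks + ``manifest.csv``
* ``train/``       ``history_<region>.csv``, ``checkpoints/<region>.npz``,
                   ``selected.json``, ``split.json``
* ``predictions.csv``  one row per (recording, region) on the test split
* ``report.json``  accuracy metrics and gap tests per region

Every stage is deterministic given the config seed; stage seeds are derived
from it with fixed offsets so stages can be rerun independently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import PREDICTIONS_COLUMNS, aggregate_segment_predictions
from .io import iter_dataset, write_manifest, write_raw
from .model import BrainAgeRegressor
from .montage import region_channels
from .preprocess import PreprocessConfig, preprocess_recording
from .recording import PredictionRecord
from .simulate import SimulationConfig, cohort_manifest, iter_cohort
from .stats import correlation_metrics, paired_gap_test
from .training import split_dataset
from .inference import records_to_frame

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "predict", "stats")

DEFAULT_CONFIG: dict = {
    "run_id": "run0",
    "seed": 0,
    "stages": list(STAGES),
    "simulate": {},          # SimulationConfig fields
    "preprocess": {},        # PreprocessConfig fields
    "train": {
        "regions": ["whole"],
        "epochs": 50,
        "lr": 1e-3,
        "batch_size": 64,
        "n_filters": 32,
        "hidden_size": 64,
        "n_gru_layers": 2,
        "loss": "mae",
        "delta_tolerance_years": 0.5,
        "split_ratios": [8, 1, 1],
        "stratify_by_age": True,
    },
    "predict": {"subset": "test"},
    "stats": {},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _graph_path(rundir: Path, recording_id: str) -> Path:
    return rundir / "graphs" / f"{recording_id}.npz"


def _load_graphs(rundir: Path, recording_id: str) -> tuple[np.ndarray, np.ndarray]:
    with np.load(_graph_path(rundir, recording_id)) as z:
        return z["values"].astype(np.float64), z["freqs_hz"]


def stage_simulate(cfg: dict, rundir: Path) -> None:
    sim_cfg = SimulationConfig.from_dict({"seed": cfg["seed"], **cfg["simulate"]})
    data_dir = rundir / "data"
    manifest = cohort_manifest(sim_cfg)
    for rec in iter_cohort(sim_cfg):
        write_raw(rec, data_dir)
    manifest.to_csv(data_dir / "ages.csv", index=False)
    logger.info("simulated %d recordings into %s", len(manifest), data_dir)


def stage_preprocess(cfg: dict, rundir: Path) -> None:
    data_dir = rundir / "data"
    if not (data_dir / "ages.csv").exists():
        raise FileNotFoundError(
            "preprocess stage: no data/ages.csv in run directory (run simulate first "
            "or point the run at an existing dataset)"
        )
    pp_cfg = PreprocessConfig.from_dict(cfg["preprocess"])
    graph_dir = rundir / "graphs"
    graph_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for rec in iter_dataset(data_dir):
        result = preprocess_recording(rec, pp_cfg)
        rows.extend(result.manifest_rows)
        if result.graphs:
            values = np.stack([g.values for g in result.graphs]).astype(np.float32)
            np.savez_compressed(
                _graph_path(rundir, rec.recording_id),
                values=values,
                freqs_hz=result.graphs[0].freqs_hz,
                age_years=rec.age_years,
                subject_id=rec.subject_id,
            )
    write_manifest(rows, graph_dir / "manifest.csv")
    logger.info("preprocessed %d segment rows", len(rows))


def stage_train(cfg: dict, rundir: Path) -> None:
    ages_path = rundir / "data" / "ages.csv"
    if not (rundir / "graphs").exists():
        raise FileNotFoundError("train stage: graphs/ missing; run preprocess first")
    ages = pd.read_csv(ages_path)
    tr = cfg["train"]
    available = [r for r in ages.itertuples() if _graph_path(rundir, r.recording_id).exists()]
    split = split_dataset(
        [r.recording_id for r in available],
        ratios=tuple(tr["split_ratios"]),
        seed=cfg["seed"] + 1,
        ages=[r.age_years for r in available] if tr.get("stratify_by_age", True) else None,
    )
    train_dir = rundir / "train"
    (train_dir / "checkpoints").mkdir(parents=True, exist_ok=True)
    (train_dir / "split.json").write_text(json.dumps(split.subsets(), indent=1))

    age_of = dict(zip(ages["recording_id"], ages["age_years"]))

    def collect(rec_ids, region):
        graphs, labels = [], []
        idx = None
        for rid in rec_ids:
            values, _ = _load_graphs(rundir, rid)
            if region != "whole" and idx is None:
                from .montage import region_indices
                from .montage import CANONICAL_19
                idx = region_indices(region, CANONICAL_19)
            if region != "whole":
                values = values[:, idx]
            graphs.append(values)
            labels.extend([age_of[rid]] * values.shape[0])
        return np.concatenate(graphs), np.asarray(labels)

    selected = {}
    for region in tr["regions"]:
        region_channels(region)
        x_train, y_train = collect(split.train, region)
        x_val, y_val = collect(split.validate, region)
        est = BrainAgeRegressor(
            n_filters=tr["n_filters"],
            hidden_size=tr["hidden_size"],
            n_gru_layers=tr["n_gru_layers"],
            region=region,
            epochs=tr["epochs"],
            lr=tr["lr"],
            batch_size=tr["batch_size"],
            loss=tr["loss"],
            delta_tolerance_years=tr["delta_tolerance_years"],
            random_state=cfg["seed"] + 2,
        )
        est.fit(x_train, y_train, validation_data=(x_val, y_val))
        est.history_.to_frame().to_csv(train_dir / f"history_{region}.csv", index=False)
        est.save_checkpoint(train_dir / "checkpoints" / f"{region}.npz")
        selected[region] = {
            "best_epoch": int(est.best_epoch_),
            "mean_mae": est.history_.records[est.best_epoch_ - 1].mean_mae,
            "delta_mae": est.history_.records[est.best_epoch_ - 1].delta_mae,
        }
        logger.info("trained %s model: %s", region, selected[region])
    (train_dir / "selected.json").write_text(
        json.dumps({"seed": cfg["seed"], "models": selected}, indent=1)
    )


def stage_predict(cfg: dict, rundir: Path) -> None:
    train_dir = rundir / "train"
    if not (train_dir / "split.json").exists():
        raise FileNotFoundError("predict stage: train/split.json missing; run train first")
    split = json.loads((train_dir / "split.json").read_text())
    subset = cfg["predict"].get("subset", "test")
    rec_ids = split[subset] if subset != "all" else sum(split.values(), [])
    ages = pd.read_csv(rundir / "data" / "ages.csv").set_index("recording_id")
    records: list[PredictionRecord] = []
    for ckpt in sorted((train_dir / "checkpoints").glob("*.npz")):
        region = ckpt.stem
        est = BrainAgeRegressor.load_checkpoint(ckpt)
        if region != "whole":
            from .montage import CANONICAL_19, region_indices
            idx = region_indices(region, CANONICAL_19)
        for rid in rec_ids:
            values, _ = _load_graphs(rundir, rid)
            if region != "whole":
                values = values[:, idx]
            ba = aggregate_segment_predictions(est.predict(values))
            records.append(
                PredictionRecord(
                    subject_id=str(ages.loc[rid, "subject_id"]),
                    recording_id=rid,
                    region=region,
                    ca_years=float(ages.loc[rid, "age_years"]),
                    ba_years=ba,
                    n_segments=values.shape[0],
                )
            )
    frame = records_to_frame(records)
    frame.to_csv(rundir / "predictions.csv", index=False)
    logger.info("wrote %d predictions", len(frame))


def stage_stats(cfg: dict, rundir: Path) -> None:
    pred_path = rundir / "predictions.csv"
    if not pred_path.exists():
        raise FileNotFoundError("stats stage: predictions.csv missing; run predict first")
    preds = pd.read_csv(pred_path)
    report: dict = {"run_id": cfg["run_id"], "version": __version__, "regions": {}}
    for region, group in preds.groupby("region"):
        entry: dict = {}
        try:
            m = correlation_metrics(group["ba_years"], group["ca_years"], region=region)
            entry["metrics"] = {"r": m.r, "p": m.p, "r2": m.r2, "mae_years": m.mae_years,
                                "n": m.n}
        except ValueError as exc:
            entry["metrics"] = {"error": str(exc)}
        try:
            g = paired_gap_test(group["brain_age_gap_years"], region=region)
            entry["gap_test"] = {"mean_gap_years": g.mean_gap_years,
                                 "sd_gap_years": g.sd_gap_years, "t": g.t, "p": g.p,
                                 "d": g.d, "n": g.n}
        except ValueError as exc:
            entry["gap_test"] = {"error": str(exc)}
        report["regions"][region] = entry
    (rundir / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("stats written for %d regions", len(report["regions"]))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "predict": stage_predict,
    "stats": stage_stats,
}


def run_pipeline(config: dict | None, out_dir) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    cfg = merge_config(config)
    rundir = Path(out_dir) / str(cfg["run_id"])
    rundir.mkdir(parents=True, exist_ok=True)
    (rundir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    handler = logging.FileHandler(rundir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("eegage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        for stage in cfg["stages"]:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
            logger.info("stage %s starting", stage)
            _STAGE_FUNCS[stage](cfg, rundir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return rundir
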