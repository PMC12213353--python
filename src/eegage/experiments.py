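"""Self-contained reproducible experiments on synthetic cohorts.

These functions tie the whole pipeline together at desk scale: simulate a
seeded cohort, preprocess, split, train, and evaluate on the held-out test
recordings. They exist so that the same experiment definition backs both the
test suite and reproduction scripts.

The default recovery experiment uses 120 subjects aged 3-14 with 6-minute
recordings, 60-s analysis windows (30-s step), a reduced 16-band filterbank
and 30 training epochs — small enough to run on one CPU in a few minutes
while leaving the architecture and every preprocessing rule identical to the
full-scale configuration.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from .model import BrainAgeRegressor
from .preprocess import PreprocessConfig, preprocess_recording
from .simulate import SimulationConfig, iter_cohort
from .stats import correlation_metrics
from .training import split_dataset


def build_cohort_graphs(
    sim_cfg: SimulationConfig, pp_cfg: PreprocessConfig
) -> tuple[dict[str, np.ndarray], dict[str, float], np.ndarray]:
    """Simulate + preprocess a cohort.

    Returns ``(graphs, ages, freqs_hz)`` where ``graphs[recording_id]`` is a
    float32 ``(n_segments, C, F, T)`` stack and ``ages`` maps recording id to
    chronological age.
    """
    graphs: dict[str, np.ndarray] = {}
    ages: dict[str, float] = {}
    freqs = None
    for rec in iter_cohort(sim_cfg):
        result = preprocess_recording(rec, pp_cfg)
        if not result.graphs:
            continue
        graphs[rec.recording_id] = np.stack(
            [g.values for g in result.graphs]
        ).astype(np.float32)
        ages[rec.recording_id] = rec.age_years
        freqs = result.graphs[0].freqs_hz
    return graphs, ages, freqs


def _stack(graphs, ages, rec_ids):
    x = np.concatenate([graphs[r] for r in rec_ids]).astype(np.float64)
    y = np.concatenate([[ages[r]] * graphs[r].shape[0] for r in rec_ids])
    return x, y


def age_recovery(
    seed: int = 7,
    n_subjects: int = 120,
    duration_seconds: float = 360.0,
    window_seconds: float = 60.0,
    step_seconds: float = 30.0,
    n_filters: int = 16,
    hidden_size: int = 64,
    epochs: int = 30,
    batch_size: int = 64,
    delta_tolerance_years: float = 0.5,
) -> dict:
    """Train a scaled-down model on a synthetic cohort; evaluate held-out recovery.

    The cohort is split 8:1:1 by recording with age stratification; the model
    is selected by the meanMAE/deltaMAE rule; test-set brain ages are medians
    over segment predictions. Returns the held-out Pearson r, MAE (years),
    per-recording predictions and the selected epoch.
    """
    sim_cfg = SimulationConfig(
        n_subjects=n_subjects, duration_seconds=duration_seconds, seed=seed
    )
    pp_cfg = PreprocessConfig(window_seconds=window_seconds, step_seconds=step_seconds)
    graphs, ages, freqs = build_cohort_graphs(sim_cfg, pp_cfg)
    rec_ids = sorted(graphs)
    split = split_dataset(
        rec_ids, seed=seed + 1, ages=[ages[r] for r in rec_ids]
    )
    x_train, y_train = _stack(graphs, ages, split.train)
    x_val, y_val = _stack(graphs, ages, split.validate)
    est = BrainAgeRegressor(
        n_filters=n_filters,
        hidden_size=hidden_size,
        epochs=epochs,
        batch_size=batch_size,
        delta_tolerance_years=delta_tolerance_years,
        freqs_hz=freqs,
        random_state=seed + 2,
    )
    est.fit(x_train, y_train, validation_data=(x_val, y_val))

    ba = np.array(
        [float(np.median(est.predict(graphs[r].astype(np.float64)))) for r in split.test]
    )
    ca = np.array([ages[r] for r in split.test])
    metrics = correlation_metrics(ba, ca)
    return {
        "r": metrics.r,
        "mae_years": metrics.mae_years,
        "n_test": metrics.n,
        "best_epoch": est.best_epoch_,
        "history": est.history_.to_frame(),
        "ba": ba,
        "ca": ca,
        "estimator": est,
        "split": split,
    }


MICRO_PIPELINE_CONFIG = {
    "run_id": "micro",
    "simulate": {"n_subjects": 10, "duration_seconds": 120.0},
    "preprocess": {"window_seconds": 60.0, "step_seconds": 30.0},
    "train": {"epochs": 3, "n_filters": 8, "hidden_size": 16, "batch_size": 16},
    "predict": {"subset": "all"},
}


def pipeline_determinism(seed: int = 0, workdir=None) -> dict:
    """Run the micro pipeline twice with one seed; compare predictions.csv bytes.

    Returns the two file contents and whether they are identical.
    """
    from .pipeline import run_pipeline

    outputs = []
    base = Path(workdir) if workdir is not None else None
    with tempfile.TemporaryDirectory(dir=base) as tmp:
        for attempt in ("a", "b"):
            cfg = dict(MICRO_PIPELINE_CONFIG)
            cfg["seed"] = seed
            rundir = run_pipeline(cfg, Path(tmp) / attempt)
            outputs.append((rundir / "predictions.csv").read_bytes())
    return {"identical": outputs[0] == outputs[1], "n_bytes": len(outputs[0])}
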