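"""Reading and writing recordings, manifests and prediction tables.

Two on-disk recording formats are supported:

* EDF/EDF+ clinical exports, read through MNE (lazy import; install the
  ``edf`` extra). Signals are converted to microvolts.
* the internal raw format: ``<recording_id>.npy`` (channels x samples,
  microvolts) plus a JSON sidecar ``<recording_id>.json`` holding
  ``subject_id, age_years, rate, channel_labels`` and optional fields.

A dataset directory is a flat folder of such pairs plus ``ages.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import RawRecording

SIDECAR_FIELDS = ("subject_id", "age_years", "rate", "channel_labels")


def read_edf(path, age_years: float = float("nan"), subject_id: str = "") -> RawRecording:
    """Load an EDF/EDF+ file as a :class:`RawRecording` (amplitudes in uV)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE works in volts
    return RawRecording(
        data=data,
        rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=subject_id or Path(path).stem,
        recording_id=Path(path).stem,
        age_years=age_years,
    )


def write_raw(rec: RawRecording, directory) -> Path:
    """Write a recording in the internal npy + JSON-sidecar format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / rec.recording_id
    np.save(base.with_suffix(".npy"), rec.data)
    sidecar = {
        "subject_id": rec.subject_id,
        "recording_id": rec.recording_id,
        "age_years": rec.age_years,
        "rate": rec.rate,
        "channel_labels": list(rec.channel_labels),
        "sex": rec.sex,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npy")


def read_raw(npy_path) -> RawRecording:
    """Load one internal-format recording from its ``.npy`` (sidecar alongside)."""
    npy_path = Path(npy_path)
    sidecar = json.loads(npy_path.with_suffix(".json").read_text())
    missing = [f for f in SIDECAR_FIELDS if f not in sidecar]
    if missing:
        raise ValueError(f"sidecar {npy_path.with_suffix('.json')} missing {missing}")
    return RawRecording(
        data=np.load(npy_path),
        rate=float(sidecar["rate"]),
        channel_labels=tuple(sidecar["channel_labels"]),
        subject_id=str(sidecar["subject_id"]),
        recording_id=str(sidecar.get("recording_id", npy_path.stem)),
        age_years=float(sidecar["age_years"]),
        sex=str(sidecar.get("sex", "")),
    )


def load_recording(path, **kwargs) -> RawRecording:
    """Dispatch on extension: ``.edf`` via MNE, ``.npy`` via the internal format."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, **kwargs)
    if path.suffix == ".npy":
        return read_raw(path)
    raise ValueError(f"unsupported recording format: {path.suffix!r}")


def iter_dataset(directory):
    """Yield recordings from a dataset directory (sorted for determinism)."""
    directory = Path(directory)
    for npy in sorted(directory.glob("*.npy")):
        yield read_raw(npy)


def write_manifest(rows: list[dict], path) -> None:
    """Segment-level bookkeeping CSV (one row per segment, retained or not)."""
    columns = ["subject_id", "recording_id", "segment_index", "start_seconds",
               "artifact_fraction", "retained"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
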