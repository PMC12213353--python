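"""Per-recording brain age via median aggregation of segment predictions.

A trained model predicts one age per retained 5-min segment; the recording's
brain age (BA) is the median of those predictions (even counts: midpoint of
the central pair), which keeps single aberrant segments from dominating. The
brain-age gap ("Brain AGE") is BA minus chronological age: positive values
read as advanced maturation, negative as delayed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .recording import PredictionRecord, RawRecording
from .preprocess import PreprocessConfig, preprocess_recording

PREDICTIONS_COLUMNS = [
    "subject_id", "recording_id", "region", "ca_years", "ba_years",
    "brain_age_gap_years", "n_segments",
]


def aggregate_segment_predictions(segment_ages: np.ndarray) -> float:
    """Median of per-segment predictions; even counts average the middle pair."""
    ages = np.asarray(segment_ages, dtype=np.float64)
    if ages.size == 0:
        raise ValueError("no segment predictions to aggregate")
    return float(np.median(ages))


def brain_age_gap(ba_years: float, ca_years: float) -> float:
    """Signed gap BA - CA in years."""
    if ba_years <= 0 or ca_years <= 0:
        raise ValueError("ages must be positive")
    return ba_years - ca_years


def predict_graphs(model, graphs, rec: RawRecording, region: str = "whole") -> PredictionRecord:
    """Predict BA for one recording from its already-computed graphs."""
    if len(graphs) == 0:
        raise ValueError(
            f"recording {rec.recording_id!r} has no retained segments; cannot predict"
        )
    seg_ages = model.predict(graphs)
    ba = aggregate_segment_predictions(seg_ages)
    return PredictionRecord(
        subject_id=rec.subject_id,
        recording_id=rec.recording_id,
        region=region,
        ca_years=rec.age_years,
        ba_years=ba,
        n_segments=len(graphs),
    )


def predict_recording(
    model,
    rec: RawRecording,
    region: str = "whole",
    cfg: PreprocessConfig | None = None,
) -> PredictionRecord:
    """Preprocess a raw recording, predict each retained segment, aggregate.

    For a regional model the region's channels are selected from the
    canonical-order graphs before prediction.
    """
    result = preprocess_recording(rec, cfg)
    graphs = result.graphs
    if region != "whole":
        from .montage import region_channels

        labels = region_channels(region)
        graphs = [g.select_channels(labels) for g in graphs]
    return predict_graphs(model, graphs, result.recording, region)


def records_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    """Predictions table with the canonical column layout."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "recording_id": r.recording_id,
                "region": r.region,
                "ca_years": r.ca_years,
                "ba_years": r.ba_years,
                "brain_age_gap_years": r.brain_age_gap_years,
                "n_segments": r.n_segments,
            }
            for r in records
        ],
        columns=PREDICTIONS_COLUMNS,
    )
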