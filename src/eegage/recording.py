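"""Core in-memory containers for EEG recordings and their derived views.

Amplitudes are microvolts throughout; time is seconds; ages are fractional
years. Channel axes follow :data:`eegage.montage.CANONICAL_19` order once a
recording has been canonicalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import CANONICAL_19, NON_SCALP_LABELS, _normalize_label


@dataclass
class RawRecording:
    """A multi-channel scalp EEG recording with subject metadata.

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    rate
        Sampling rate in samples/second.
    channel_labels
        One 10-20 electrode name per row of ``data``.
    subject_id
        Opaque subject identifier.
    age_years
        Chronological age (CA) at recording time, fractional years.
    recording_id
        Distinguishes repeat recordings of one subject.
    """

    data: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    age_years: float = float("nan")
    recording_id: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.recording_id:
            self.recording_id = self.subject_id

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.data.shape[1] / self.rate

    def with_data(self, data: np.ndarray, rate: float | None = None) -> "RawRecording":
        """Copy of this recording with new signal content, same metadata."""
        return replace(self, data=data, rate=self.rate if rate is None else rate)

    def canonicalize(self, strict: bool = True) -> "RawRecording":
        """Reorder channels to the canonical 19-name montage.

        Vendor label variants are normalized, non-scalp channels (auricular
        references, ECG, ...) are dropped. With ``strict`` every canonical
        electrode must be present; otherwise the available subset is kept in
        canonical order.
        """
        normalized = [_normalize_label(l) for l in self.channel_labels]
        keep: list[tuple[str, int]] = []
        for name in CANONICAL_19:
            if name in normalized:
                keep.append((name, normalized.index(name)))
            elif strict:
                raise ValueError(f"electrode {name!r} missing from recording")
        dropped = set(normalized) - {n for n, _ in keep}
        unexpected = dropped - NON_SCALP_LABELS - set(CANONICAL_19)
        # unexpected extras are dropped too; canonical order is the contract
        del unexpected
        labels = tuple(n for n, _ in keep)
        rows = [i for _, i in keep]
        return replace(self, data=self.data[rows], channel_labels=labels)


@dataclass
class Segment:
    """A fixed-length window cut from a recording.

    ``artifact_fraction`` is the share of samples inside the window where the
    amplitude-threshold artifact mask is true on at least one channel.
    """

    data: np.ndarray
    rate: float
    start_seconds: float
    artifact_fraction: float
    channel_labels: tuple[str, ...] = ()
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1]")

    @property
    def duration_seconds(self) -> float:
        return self.data.shape[1] / self.rate


@dataclass
class TimeFrequencyGraph:
    """Per-segment spectral representation: channels x frequency bins x frames."""

    values: np.ndarray
    freqs_hz: np.ndarray
    frame_times: np.ndarray
    channel_labels: tuple[str, ...] = ()
    scale: str = "log_power"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        c, f, t = self.values.shape
        if f != self.freqs_hz.size:
            raise ValueError(f"{f} frequency rows but {self.freqs_hz.size} bin centers")
        if t != self.frame_times.size:
            raise ValueError(f"{t} frames but {self.frame_times.size} frame times")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs_hz must be strictly ascending")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def select_channels(self, labels: list[str] | tuple[str, ...]) -> "TimeFrequencyGraph":
        idx = [self.channel_labels.index(l) for l in labels]
        return TimeFrequencyGraph(
            values=self.values[idx],
            freqs_hz=self.freqs_hz,
            frame_times=self.frame_times,
            channel_labels=tuple(labels),
            scale=self.scale,
        )


@dataclass
class PredictionRecord:
    """One brain-age estimate for one recording and one regional model."""

    subject_id: str
    recording_id: str
    region: str
    ca_years: float
    ba_years: float
    n_segments: int
    brain_age_gap_years: float = field(init=False)

    def __post_init__(self) -> None:
        if self.ba_years <= 0:
            raise ValueError("brain age must be strictly positive")
        if self.n_segments < 1:
            raise ValueError("a prediction needs at least one segment")
        self.brain_age_gap_years = self.ba_years - self.ca_years
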