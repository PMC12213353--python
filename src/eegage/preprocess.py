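"""Raw EEG to retained time-frequency segments.

The chain is fixed: resample to the target rate, common average reference,
1-70 Hz band-pass, amplitude-threshold artifact mask, sliding-window
segmentation (5-min window, 30-s step by default), retention of segments with
artifact fraction < 0.30, then a Hanning-window STFT truncated to 1-40 Hz.

At the defaults (200 Hz, 4-s window, 50% overlap) a 5-min segment maps to a
19 x 157 x 149 time-frequency graph: 157 bins with centers in [1, 40] Hz at
0.25 Hz resolution, 149 frames of 800 samples hopped by 400.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .recording import RawRecording, Segment, TimeFrequencyGraph

logger = logging.getLogger(__name__)

LOG_POWER_EPS = 1e-10


@dataclass
class PreprocessConfig:
    """Tunables of the preprocessing chain (defaults follow the study protocol)."""

    target_rate: float = 200.0
    band: tuple[float, float] = (1.0, 70.0)
    artifact_threshold_uv: float = 200.0
    window_seconds: float = 300.0
    step_seconds: float = 30.0
    max_artifact_fraction: float = 0.30
    stft_window_seconds: float = 4.0
    stft_overlap: float = 0.5
    spec_band: tuple[float, float] = (1.0, 40.0)
    spec_scale: str = "log_power"  # magnitude | power | log_power
    filter_taps: int = 401

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        kwargs = dict(d)
        for key in ("band", "spec_band"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def resample_recording(rec: RawRecording, target_rate: float) -> RawRecording:
    """Polyphase anti-aliased downsampling to ``target_rate``.

    Upsampling is refused: the pipeline only ever reduces clinical rates
    (>= 500 Hz) to the 200 Hz working rate.
    """
    if target_rate > rec.rate:
        raise ValueError(
            f"upsampling not supported: recording at {rec.rate} Hz, requested {target_rate} Hz"
        )
    if target_rate == rec.rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return rec.with_data(data, rate=target_rate)


def common_average_reference(rec: RawRecording) -> RawRecording:
    """Re-reference each channel against the instantaneous mean of all channels."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def bandpass_filter(
    rec: RawRecording, low_hz: float, high_hz: float, numtaps: int = 401
) -> RawRecording:
    """Zero-phase FIR band-pass (forward-backward application of a linear-phase FIR)."""
    nyquist = rec.rate / 2.0
    if not 0.0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz must lie below the Nyquist rate {nyquist} Hz"
        )
    if numtaps % 2 == 0:
        numtaps += 1
    taps = signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=rec.rate)
    padlen = min(3 * numtaps, rec.n_samples - 1)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=1, padlen=padlen)
    return rec.with_data(data)


def artifact_mask(rec: RawRecording, amplitude_threshold_uv: float = 200.0) -> np.ndarray:
    """Per-sample boolean mask: true where |amplitude| exceeds the threshold on ANY channel."""
    if amplitude_threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    return np.any(np.abs(rec.data) > amplitude_threshold_uv, axis=0)


def segment_recording(
    rec: RawRecording,
    window_seconds: float = 300.0,
    step_seconds: float = 30.0,
    mask: np.ndarray | None = None,
) -> list[Segment]:
    """Cut sliding windows of ``window_seconds`` every ``step_seconds``.

    Windows start at 0, step, 2*step, ...; a recording shorter than one window
    yields an empty list. Each segment carries the artifact fraction computed
    from ``mask`` (all-clean if no mask is given).
    """
    n_window = int(round(window_seconds * rec.rate))
    n_step = int(round(step_seconds * rec.rate))
    if rec.n_samples < n_window:
        logger.info(
            "recording %s shorter than window (%.1f s < %.1f s); no segments",
            rec.recording_id, rec.duration_seconds, window_seconds,
        )
        return []
    if mask is None:
        mask = np.zeros(rec.n_samples, dtype=bool)
    n_seg = (rec.n_samples - n_window) // n_step + 1
    segments = []
    for k in range(n_seg):
        start = k * n_step
        sl = slice(start, start + n_window)
        segments.append(
            Segment(
                data=rec.data[:, sl],
                rate=rec.rate,
                start_seconds=start / rec.rate,
                artifact_fraction=float(mask[sl].mean()),
                channel_labels=rec.channel_labels,
                index=k,
            )
        )
    return segments


def retain_segments(
    segments: list[Segment], max_artifact_fraction: float = 0.30
) -> list[Segment]:
    """Keep segments whose artifact fraction is strictly below the cutoff, in order."""
    return [s for s in segments if s.artifact_fraction < max_artifact_fraction]


def stft_graph(
    seg: Segment,
    window_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
    band_hz: tuple[float, float] = (1.0, 40.0),
    scale: str = "log_power",
    eps: float = LOG_POWER_EPS,
) -> TimeFrequencyGraph:
    """Hanning-window STFT of a segment, truncated to ``band_hz`` (inclusive).

    Frames are hopped by ``window * (1 - overlap)`` starting at sample 0, so
    the frame count is ``floor((n_samples - n_window)/hop) + 1``. ``scale``
    selects |X| (magnitude), |X|^2 (power) or log(|X|^2 + eps) (log_power,
    default — log compression keeps the downstream trainable filters and
    recurrent layers in a well-behaved numeric range).
    """
    n_window = int(round(window_seconds * seg.rate))
    hop = int(round(n_window * (1.0 - overlap_fraction)))
    if n_window > seg.data.shape[1]:
        raise ValueError(
            f"STFT window ({n_window} samples) longer than segment ({seg.data.shape[1]})"
        )
    win = signal.windows.hann(n_window, sym=False)
    frames = sliding_window_view(seg.data, n_window, axis=1)[:, ::hop, :]
    spec = np.fft.rfft(frames * win, axis=2)  # (C, T, F_full)
    freqs = np.fft.rfftfreq(n_window, d=1.0 / seg.rate)
    lo, hi = band_hz
    keep = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    mag = np.abs(spec[:, :, keep]).transpose(0, 2, 1)  # (C, F, T)
    if scale == "magnitude":
        values = mag
    elif scale == "power":
        values = mag**2
    elif scale == "log_power":
        values = np.log(mag**2 + eps)
    else:
        raise ValueError(f"unknown spectrogram scale {scale!r}")
    n_frames = mag.shape[2]
    frame_times = (np.arange(n_frames) * hop + n_window / 2.0) / seg.rate
    return TimeFrequencyGraph(
        values=values,
        freqs_hz=freqs[keep],
        frame_times=frame_times,
        channel_labels=seg.channel_labels,
        scale=scale,
    )


def expected_stft_shape(
    segment_seconds: float = 300.0,
    rate: float = 200.0,
    window_seconds: float = 4.0,
    overlap_fraction: float = 0.5,
    band_hz: tuple[float, float] = (1.0, 40.0),
) -> tuple[int, int]:
    """(F, T) the STFT settings imply, from the frame/bin counting formulas."""
    n = int(round(segment_seconds * rate))
    n_window = int(round(window_seconds * rate))
    hop = int(round(n_window * (1.0 - overlap_fraction)))
    n_frames = (n - n_window) // hop + 1
    resolution = rate / n_window
    lo, hi = band_hz
    first = math.ceil(lo / resolution - 1e-9)
    last = math.floor(hi / resolution + 1e-9)
    return last - first + 1, n_frames


@dataclass
class PreprocessResult:
    """Retained segments and graphs of one recording plus per-segment bookkeeping."""

    recording: RawRecording
    segments: list[Segment]
    graphs: list[TimeFrequencyGraph]
    manifest_rows: list[dict] = field(default_factory=list)


def preprocess_recording(
    rec: RawRecording, cfg: PreprocessConfig | None = None, canonicalize: bool = True
) -> PreprocessResult:
    """Run the full chain on one recording.

    Order is fixed: canonicalize -> resample -> common average reference ->
    band-pass -> artifact mask -> segment -> retain -> STFT.
    """
    cfg = cfg or PreprocessConfig()
    if canonicalize:
        rec = rec.canonicalize()
    rec = resample_recording(rec, cfg.target_rate)
    rec = common_average_reference(rec)
    rec = bandpass_filter(rec, *cfg.band, numtaps=cfg.filter_taps)
    mask = artifact_mask(rec, cfg.artifact_threshold_uv)
    segments = segment_recording(rec, cfg.window_seconds, cfg.step_seconds, mask)
    retained = retain_segments(segments, cfg.max_artifact_fraction)
    graphs = [
        stft_graph(s, cfg.stft_window_seconds, cfg.stft_overlap, cfg.spec_band, cfg.spec_scale)
        for s in retained
    ]
    retained_idx = {s.index for s in retained}
    rows = [
        {
            "subject_id": rec.subject_id,
            "recording_id": rec.recording_id,
            "segment_index": s.index,
            "start_seconds": s.start_seconds,
            "artifact_fraction": s.artifact_fraction,
            "retained": s.index in retained_idx,
        }
        for s in segments
    ]
    return PreprocessResult(recording=rec, segments=retained, graphs=graphs, manifest_rows=rows)
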