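"""Seeded synthetic pediatric EEG cohorts with an age-dependent spectral signature.

The generator emulates awake resting-state scalp EEG on the 19-channel 10-20
montage. Each recording is the sum of

* a 1/f^beta background (white noise shaped in the frequency domain),
  independent per channel;
* a posterior dominant rhythm (PDR): a narrow-band oscillation whose peak
  frequency matures with age along a saturating-exponential curve

      f_pdr(age) = asymptote - (asymptote - base) * exp(-age / rate_constant)

  (defaults 6 Hz base, 10 Hz asymptote, 4-year rate constant: ~8.5 Hz at age
  4, approaching 10 Hz in adolescence). The rhythm is amplitude-modulated by
  slow positive envelope noise, largest on O1/O2 and fading anteriorly;
* white sensor noise;
* Poisson-placed high-amplitude artifact bursts that exceed the 200 uV
  artifact threshold, so the preprocessing mask has something to find.

Everything is driven by one seed; a cohort draw is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import CANONICAL_19
from .recording import RawRecording

#: Relative PDR amplitude per channel: occipital-dominant posterior gradient.
_PDR_TOPOGRAPHY = {
    "O1": 1.0, "O2": 1.0, "P3": 0.65, "P4": 0.65, "Pz": 0.65,
    "T5": 0.45, "T6": 0.45, "C3": 0.25, "C4": 0.25, "Cz": 0.25,
    "T3": 0.2, "T4": 0.2, "F3": 0.12, "F4": 0.12, "Fz": 0.12,
    "F7": 0.1, "F8": 0.1, "Fp1": 0.08, "Fp2": 0.08,
}


@dataclass
class SimulationConfig:
    """Cohort-level generator settings (amplitudes in uV, rates in Hz)."""

    n_subjects: int = 120
    age_range_years: tuple[float, float] = (3.0, 14.0)
    rate: float = 200.0
    duration_seconds: float = 360.0
    channel_labels: tuple[str, ...] = CANONICAL_19
    pdr_base_hz: float = 6.0
    pdr_asymptote_hz: float = 10.0
    pdr_rate_constant_years: float = 4.0
    pdr_amplitude_uv: float = 30.0
    background_exponent: float = 1.0
    background_sd_uv: float = 15.0
    noise_sd_uv: float = 5.0
    artifact_rate_per_minute: float = 1.0
    artifact_amplitude_uv: float = 300.0
    artifact_duration_seconds: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pdr_asymptote_hz > 40.0:
            raise ValueError("PDR asymptote must stay inside the 1-40 Hz analysis band")
        if 0 < self.artifact_rate_per_minute and self.artifact_amplitude_uv <= 200.0:
            raise ValueError("artifact bursts must exceed the 200 uV mask threshold")
        for name in ("rate", "duration_seconds", "noise_sd_uv", "background_sd_uv",
                     "artifact_rate_per_minute"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = dict(d)
        if "age_range_years" in kwargs:
            kwargs["age_range_years"] = tuple(kwargs["age_range_years"])
        if "channel_labels" in kwargs:
            kwargs["channel_labels"] = tuple(kwargs["channel_labels"])
        return cls(**kwargs)


def pdr_frequency(age_years, cfg: SimulationConfig) -> np.ndarray | float:
    """Posterior-rhythm peak frequency at a given age (saturating exponential)."""
    age = np.asarray(age_years, dtype=np.float64)
    f = cfg.pdr_asymptote_hz - (cfg.pdr_asymptote_hz - cfg.pdr_base_hz) * np.exp(
        -age / cfg.pdr_rate_constant_years
    )
    return float(f) if np.isscalar(age_years) else f


def _one_over_f_noise(rng: np.random.Generator, n: int, rate: float, exponent: float,
                      sd: float) -> np.ndarray:
    """White noise spectrally shaped to 1/f^exponent, scaled to target sd."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n=n)
    return shaped * (sd / shaped.std())


def _slow_envelope(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Positive slow (~0.1 Hz) amplitude modulation around 1 (waxing/waning)."""
    n_slow = max(4, int(n * 0.1 / rate) + 2)  # control points every ~10 s
    coarse = rng.standard_normal(n_slow)
    t = np.linspace(0.0, 1.0, n)
    envelope = np.interp(t, np.linspace(0.0, 1.0, n_slow), coarse)
    envelope = 1.0 + 0.4 * envelope / max(np.abs(envelope).max(), 1e-12)
    return np.clip(envelope, 0.1, None)


def simulate_recording(
    age_years: float,
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    subject_id: str = "sim",
    recording_id: str = "",
    sex: str = "",
) -> RawRecording:
    """One seeded recording at the given age; fully determined by (cfg, seed)."""
    cfg = cfg or SimulationConfig()
    lo, hi = cfg.age_range_years
    if not lo <= age_years <= hi:
        raise ValueError(f"age {age_years} outside configured range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_seconds * cfg.rate))
    n_chan = len(cfg.channel_labels)
    t = np.arange(n) / cfg.rate
    data = np.empty((n_chan, n))

    f_pdr = pdr_frequency(age_years, cfg)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    envelope = _slow_envelope(rng, n, cfg.rate)
    rhythm = np.sin(2.0 * np.pi * f_pdr * t + phase) * envelope

    for c, label in enumerate(cfg.channel_labels):
        background = _one_over_f_noise(
            rng, n, cfg.rate, cfg.background_exponent, cfg.background_sd_uv
        )
        sensor = rng.standard_normal(n) * cfg.noise_sd_uv
        topo = _PDR_TOPOGRAPHY.get(label, 0.1)
        data[c] = background + sensor + cfg.pdr_amplitude_uv * topo * rhythm

    # Poisson-placed artifact bursts: in-band (8 Hz) oscillations under a Hann
    # envelope, so they still exceed the mask threshold after the 1-70 Hz
    # band-pass that precedes artifact identification
    n_events = rng.poisson(cfg.artifact_rate_per_minute * cfg.duration_seconds / 60.0)
    n_burst = max(1, int(round(cfg.artifact_duration_seconds * cfg.rate)))
    t_burst = np.arange(n_burst) / cfg.rate
    pulse = np.sin(2.0 * np.pi * 8.0 * t_burst) * np.hanning(n_burst)
    for _ in range(n_events):
        start = int(rng.integers(0, max(1, n - n_burst)))
        channels = rng.choice(n_chan, size=int(rng.integers(1, 5)), replace=False)
        sign = rng.choice((-1.0, 1.0))
        data[np.ix_(channels, np.arange(start, start + n_burst))] += (
            sign * 1.5 * cfg.artifact_amplitude_uv * pulse
        )

    return RawRecording(
        data=data,
        rate=cfg.rate,
        channel_labels=cfg.channel_labels,
        subject_id=subject_id,
        recording_id=recording_id or subject_id,
        age_years=float(age_years),
        sex=sex,
    )


@dataclass
class SimulatedCohort:
    """Recordings plus the per-subject age table."""

    recordings: list[RawRecording]
    ages: pd.DataFrame = field(repr=False)
    config: SimulationConfig | None = None


def cohort_manifest(cfg: SimulationConfig | None = None) -> pd.DataFrame:
    """Per-subject table (ids, ages, sexes, per-recording seeds) a cohort draw will use."""
    cfg = cfg or SimulationConfig()
    if cfg.n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.age_range_years
    ages = rng.uniform(lo, hi, size=cfg.n_subjects)
    sexes = rng.choice(("M", "F"), size=cfg.n_subjects)
    seeds = rng.integers(0, 2**31 - 1, size=cfg.n_subjects)
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(cfg.n_subjects)],
            "recording_id": [f"sub{i:04d}_r0" for i in range(cfg.n_subjects)],
            "age_years": ages.astype(float),
            "sex": sexes.astype(str),
            "seed": seeds.astype(int),
        }
    )


def iter_cohort(cfg: SimulationConfig | None = None):
    """Yield cohort recordings one at a time (memory-light alternative to
    :func:`simulate_cohort`); the draw is identical to the eager version."""
    cfg = cfg or SimulationConfig()
    manifest = cohort_manifest(cfg)
    for row in manifest.itertuples():
        yield simulate_recording(
            float(row.age_years), cfg, seed=int(row.seed), subject_id=row.subject_id,
            recording_id=row.recording_id, sex=row.sex,
        )


def simulate_cohort(cfg: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw a cohort: ages uniform over the configured range, one recording each.

    Per-recording seeds are spawned from the cohort seed, so the cohort is
    reproducible as a whole and each recording individually.
    """
    cfg = cfg or SimulationConfig()
    manifest = cohort_manifest(cfg)
    return SimulatedCohort(recordings=list(iter_cohort(cfg)), ages=manifest, config=cfg)
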