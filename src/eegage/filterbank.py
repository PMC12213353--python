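"""Trainable triangular filterbank on a compressive log-frequency scale.

The filter layer reduces the frequency axis of a time-frequency graph from F
bins to M bands (M < F). Each band is a triangular window whose corners sit
at consecutive points of a grid that is uniform in log-frequency, so bands
are narrow at low frequencies and wide at high frequencies, as in Mel
filterbank design. The fixed triangular mask ``W_L`` is modulated
element-wise by ``sigmoid(W)`` with ``W`` trainable, giving the effective
filters ``W_f = sigmoid(W) * W_L`` with ``0 <= W_f <= W_L`` everywhere.

The log-frequency map is ``v = 26.0 * log10(1 + f / 7.0)`` with exact inverse
``f = 7.0 * (10^(v/26.0) - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

LOG_SCALE_A = 26.0
LOG_SCALE_B_HZ = 7.0


def hz_to_log(f_hz):
    """Map frequency (Hz) to the compressive log scale; strictly increasing on [0, inf)."""
    f = np.asarray(f_hz, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = LOG_SCALE_A * np.log10(1.0 + f / LOG_SCALE_B_HZ)
    return float(out) if np.isscalar(f_hz) else out


def log_to_hz(v):
    """Exact inverse of :func:`hz_to_log`."""
    val = np.asarray(v, dtype=np.float64)
    out = LOG_SCALE_B_HZ * (10.0 ** (val / LOG_SCALE_A) - 1.0)
    return float(out) if np.isscalar(v) else out


def filter_boundaries(
    n_filters: int,
    f_min_hz: float,
    f_max_hz: float,
    n_bins: int,
    bin_resolution_hz: float,
) -> np.ndarray:
    """M+2 strictly increasing integer bin positions for M triangular filters.

    The corners are uniform in log-frequency between ``f_min`` and ``f_max``,
    back-transformed to Hz and snapped to the nearest frequency bin. Snapping
    can collide adjacent corners at low frequencies, so strict increase is
    enforced afterwards; if that pushes past the last bin, M is too large for
    this resolution.
    """
    if n_filters < 1:
        raise ValueError("need at least one filter")
    if n_filters >= n_bins:
        raise ValueError(f"n_filters ({n_filters}) must be < n_bins ({n_bins})")
    lo, hi = hz_to_log(f_min_hz), hz_to_log(f_max_hz)
    corners_hz = log_to_hz(np.linspace(lo, hi, n_filters + 2))
    bins = np.rint((corners_hz - f_min_hz) / bin_resolution_hz).astype(int)
    for i in range(1, bins.size):
        if bins[i] <= bins[i - 1]:
            bins[i] = bins[i - 1] + 1
    if bins[-1] > n_bins - 1:
        raise ValueError(
            f"{n_filters} filters do not fit in {n_bins} bins at this resolution; "
            "reduce n_filters"
        )
    bins[-1] = n_bins - 1  # anchor the last corner at the band edge
    return bins


def build_mask(boundary_bins: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed triangular mask ``W_L`` of shape (F, M).

    Column m rises linearly from 0 at corner m to 1 at corner m+1 and falls
    back to 0 at corner m+2; it is exactly 1 at its center bin and 0 outside
    its support.
    """
    b = np.asarray(boundary_bins, dtype=int)
    if np.any(np.diff(b) <= 0):
        raise ValueError("boundary bins must be strictly increasing")
    n_filters = b.size - 2
    k = np.arange(n_bins, dtype=np.float64)[:, None]
    left, center, right = (
        b[:-2][None, :].astype(float),
        b[1:-1][None, :].astype(float),
        b[2:][None, :].astype(float),
    )
    rise = (k - left) / (center - left)
    fall = (right - k) / (right - center)
    mask = np.minimum(rise, fall)
    mask = np.clip(mask, 0.0, 1.0)
    assert mask.shape == (n_bins, n_filters)
    return mask


@dataclass
class TriangularFilterbank:
    """Fixed triangular mask plus trainable weights forming the filter layer.

    Attributes
    ----------
    mask
        ``W_L``, (F, M) constants in [0, 1], column peaks exactly 1.
    weights
        ``W``, (F, M) unconstrained trainable reals (shared across channels).
    boundary_bins
        The M+2 corner bin positions.
    freqs_hz
        Bin centers of the F-bin frequency axis.
    """

    mask: np.ndarray
    weights: np.ndarray
    boundary_bins: np.ndarray
    freqs_hz: np.ndarray

    @classmethod
    def create(
        cls,
        n_filters: int,
        freqs_hz: np.ndarray,
        rng: np.random.Generator | None = None,
        init_scale: float = 1.0,
    ) -> "TriangularFilterbank":
        """Build the mask for a given frequency axis and initialize ``W ~ N(0, init_scale)``."""
        freqs_hz = np.asarray(freqs_hz, dtype=np.float64)
        n_bins = freqs_hz.size
        resolution = float(np.mean(np.diff(freqs_hz)))
        bounds = filter_boundaries(
            n_filters, float(freqs_hz[0]), float(freqs_hz[-1]), n_bins, resolution
        )
        mask = build_mask(bounds, n_bins)
        rng = rng or np.random.default_rng(0)
        weights = rng.normal(0.0, init_scale, size=mask.shape)
        return cls(mask=mask, weights=weights, boundary_bins=bounds, freqs_hz=freqs_hz)

    @property
    def n_bins(self) -> int:
        return self.mask.shape[0]

    @property
    def n_filters(self) -> int:
        return self.mask.shape[1]

    def effective_filters(self) -> np.ndarray:
        """``W_f = sigmoid(W) * W_L``; elementwise in [0, W_L]."""
        return expit(self.weights) * self.mask

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Apply the filterbank along the frequency axis.

        ``values`` is (C, F, T) or (N, C, F, T); the F axis contracts to M.
        """
        wf = self.effective_filters()
        if values.shape[-2] != self.n_bins:
            raise ValueError(
                f"frequency axis has {values.shape[-2]} bins, filterbank expects {self.n_bins}"
            )
        return np.einsum("fm,...ft->...mt", wf, values)

    def center_frequencies_hz(self) -> np.ndarray:
        """Peak frequency of each band."""
        return self.freqs_hz[self.boundary_bins[1:-1]]

    def bandwidths_hz(self) -> np.ndarray:
        """Support width (right corner minus left corner) of each band, Hz."""
        return self.freqs_hz[self.boundary_bins[2:]] - self.freqs_hz[self.boundary_bins[:-2]]


def apply_filterbank(bank: TriangularFilterbank, values: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`TriangularFilterbank.apply`."""
    return bank.apply(values)
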