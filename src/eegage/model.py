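"""Scikit-learn style estimator for EEG brain-age regression.

:class:`BrainAgeRegressor` wraps the trainable triangular filterbank, the
unidirectional GRU stack, attention pooling over time frames and the
softplus output head into a ``fit``/``predict`` estimator operating on
time-frequency graphs. One estimator models one channel set (whole scalp or
one region); regional models are independent fits on the region's channels.

Training minimizes the mean absolute error between predicted and
chronological age with Adam. After every epoch the train and validation MAE
are recorded; the returned weights are those of the epoch selected by the
meanMAE/deltaMAE rule (:func:`eegage.training.select_model`).
"""

from __future__ import annotations

import io
import json

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from ._nn import AgeNet, Adam, attention_pool, softplus  # noqa: F401 (re-export)
from .filterbank import TriangularFilterbank
from .montage import region_channels
from .recording import TimeFrequencyGraph
from .training import EpochRecord, TrainingHistory, select_model

CHECKPOINT_SCHEMA = 1


def _coerce_graphs(X, freqs_hz=None):
    """Accept an (N, C, F, T) array or a list of TimeFrequencyGraph."""
    if isinstance(X, TimeFrequencyGraph):
        X = [X]
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], TimeFrequencyGraph):
        freqs = X[0].freqs_hz
        arr = np.stack([g.values for g in X]).astype(np.float64)
        return arr, freqs
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected (N, C, F, T) input, got shape {arr.shape}")
    if freqs_hz is None:
        freqs_hz = np.linspace(1.0, 40.0, arr.shape[2])
    return arr, np.asarray(freqs_hz, dtype=np.float64)


class BrainAgeRegressor(RegressorMixin, BaseEstimator):
    """Brain-age regression network over EEG time-frequency graphs.

    Parameters
    ----------
    n_filters : int, default 32
        Number of triangular bands M the filter layer keeps (M < F).
    hidden_size : int, default 64
        GRU hidden width H1.
    n_gru_layers : int, default 2
        Stacked unidirectional GRU layers L1.
    region : str, default "whole"
        Channel set this model is trained for; bookkeeping only — callers
        slice channels before fit (see :func:`eegage.montage.region_channels`).
    epochs, lr, batch_size, loss
        Adam optimization settings; ``loss`` is ``"mae"`` (default) or ``"mse"``.
    delta_tolerance_years : float, default 0.5
        Threshold on deltaMAE in the epoch-selection rule.
    validation_fraction : float, default 0.1
        Used only when ``fit`` is not given an explicit validation set.
    standardize : bool, default True
        Z-score each (channel, frequency-bin) feature of the log-power graph
        over the training set before the filter layer.
    freqs_hz : array or None
        Frequency-bin centers; taken from input graphs when available.
    random_state : int, default 0
        Seeds weight init, batching and the internal validation split.

    Attributes
    ----------
    net_ : AgeNet
        The fitted network (weights of the selected epoch).
    filterbank_ : TriangularFilterbank
        Mask, trainable weights and corner bins of the filter layer.
    history_ : TrainingHistory
        Per-epoch loss / MAE_train / MAE_validate.
    best_epoch_ : int
        Epoch chosen by the meanMAE/deltaMAE rule (1-based).
    input_mean_, input_scale_ : ndarray (C, F)
        Standardization statistics (zeros/ones when ``standardize=False``).
    """

    def __init__(
        self,
        n_filters: int = 32,
        hidden_size: int = 64,
        n_gru_layers: int = 2,
        region: str = "whole",
        epochs: int = 50,
        lr: float = 1e-3,
        batch_size: int = 64,
        loss: str = "mae",
        delta_tolerance_years: float = 0.5,
        validation_fraction: float = 0.1,
        standardize: bool = True,
        fb_init_scale: float = 1.0,
        freqs_hz=None,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.hidden_size = hidden_size
        self.n_gru_layers = n_gru_layers
        self.region = region
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.loss = loss
        self.delta_tolerance_years = delta_tolerance_years
        self.validation_fraction = validation_fraction
        self.standardize = standardize
        self.fb_init_scale = fb_init_scale
        self.freqs_hz = freqs_hz
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _standardize(self, arr: np.ndarray) -> np.ndarray:
        return (arr - self.input_mean_[None, :, :, None]) / self.input_scale_[None, :, :, None]

    def fit(self, X, y, validation_data=None):
        """Fit on graphs ``X`` with chronological ages ``y`` (years).

        ``validation_data=(X_val, y_val)`` supplies the validation set used
        for the per-epoch MAE bookkeeping; without it a random
        ``validation_fraction`` of the samples is held out.
        """
        region_channels(self.region)  # validate the name early
        arr, freqs = _coerce_graphs(X, self.freqs_hz)
        y = np.asarray(y, dtype=np.float64)
        if y.shape[0] != arr.shape[0]:
            raise ValueError("X and y disagree on sample count")
        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            val_arr, _ = _coerce_graphs(validation_data[0], self.freqs_hz)
            val_y = np.asarray(validation_data[1], dtype=np.float64)
            train_arr, train_y = arr, y
        else:
            n_val = max(1, int(round(self.validation_fraction * arr.shape[0])))
            if arr.shape[0] - n_val < 1:
                raise ValueError("too few samples to hold out a validation set")
            order = rng.permutation(arr.shape[0])
            val_arr, val_y = arr[order[:n_val]], y[order[:n_val]]
            train_arr, train_y = arr[order[n_val:]], y[order[n_val:]]

        n_channels, n_bins = train_arr.shape[1], train_arr.shape[2]
        if self.standardize:
            self.input_mean_ = train_arr.mean(axis=(0, 3))
            sd = train_arr.std(axis=(0, 3))
            self.input_scale_ = np.where(sd > 1e-12, sd, 1.0)
        else:
            self.input_mean_ = np.zeros((n_channels, n_bins))
            self.input_scale_ = np.ones((n_channels, n_bins))
        train_z = self._standardize(train_arr)
        val_z = self._standardize(val_arr)

        self.filterbank_ = TriangularFilterbank.create(
            self.n_filters, freqs, rng=rng, init_scale=self.fb_init_scale
        )
        net = AgeNet(
            n_channels=n_channels,
            fb_mask=self.filterbank_.mask,
            hidden_size=self.hidden_size,
            n_gru_layers=self.n_gru_layers,
            rng=rng,
            fb_init_scale=self.fb_init_scale,
        )
        net.fb_W[...] = self.filterbank_.weights
        optimizer = Adam(net.parameters(), lr=self.lr)

        history = TrainingHistory()
        best_tol = (np.inf, -1, None)   # (mean_mae, epoch, params) with delta <= tol
        best_any = (np.inf, -1, None)
        n_train = train_arr.shape[0]
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n_train)
            losses = []
            for start in range(0, n_train, self.batch_size):
                idx = order[start:start + self.batch_size]
                value, _, grads = net.loss_and_grads(train_z[idx], train_y[idx], loss=self.loss)
                optimizer.step(grads)
                losses.append(value)
            mae_train = float(np.abs(net.predict(train_z) - train_y).mean())
            mae_val = float(np.abs(net.predict(val_z) - val_y).mean())
            rec = EpochRecord(epoch, float(np.mean(losses)), mae_train, mae_val)
            history.append(rec)
            if rec.delta_mae <= self.delta_tolerance_years and rec.mean_mae < best_tol[0]:
                best_tol = (rec.mean_mae, epoch, net.copy_parameters())
            if rec.mean_mae < best_any[0]:
                best_any = (rec.mean_mae, epoch, net.copy_parameters())

        self.history_ = history
        self.best_epoch_ = select_model(history, self.delta_tolerance_years)
        chosen = best_tol if best_tol[1] == self.best_epoch_ else best_any
        net.set_parameters(chosen[2])
        self.net_ = net
        self.filterbank_.weights = net.fb_W
        self.freqs_hz_ = freqs
        self.n_channels_ = n_channels
        self.n_features_in_ = n_channels * n_bins
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted brain age in years, one strictly positive value per graph."""
        check_is_fitted(self, "net_")
        arr, _ = _coerce_graphs(X, getattr(self, "freqs_hz_", None))
        return self.net_.predict(self._standardize(arr))

    def attention_scores(self, X) -> np.ndarray:
        """Per-frame attention weights (N, T); each row sums to 1."""
        check_is_fitted(self, "net_")
        arr, _ = _coerce_graphs(X, getattr(self, "freqs_hz_", None))
        _, cache = self.net_.forward(self._standardize(arr), want_cache=True)
        return cache["scores"]

    # ------------------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        """Single-file archive: config, filterbank state, weights, history."""
        check_is_fitted(self, "net_")
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "params": self.get_params(),
            "best_epoch": int(self.best_epoch_),
            "n_channels": int(self.n_channels_),
        }
        meta["params"].pop("freqs_hz", None)
        buf = io.StringIO()
        self.history_.to_frame().to_csv(buf, index=False)
        arrays = {f"weight::{k}": v for k, v in self.net_.parameters().items()}
        np.savez(
            path,
            meta=json.dumps(meta),
            history_csv=buf.getvalue(),
            freqs_hz=self.freqs_hz_,
            fb_mask=self.filterbank_.mask,
            fb_boundaries=self.filterbank_.boundary_bins,
            input_mean=self.input_mean_,
            input_scale=self.input_scale_,
            **arrays,
        )

    @classmethod
    def load_checkpoint(cls, path) -> "BrainAgeRegressor":
        import pandas as pd

        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
            est = cls(**meta["params"])
            est.freqs_hz_ = archive["freqs_hz"]
            est.input_mean_ = archive["input_mean"]
            est.input_scale_ = archive["input_scale"]
            est.n_channels_ = meta["n_channels"]
            est.best_epoch_ = meta["best_epoch"]
            est.history_ = TrainingHistory.from_frame(
                pd.read_csv(io.StringIO(str(archive["history_csv"])))
            )
            mask = archive["fb_mask"]
            weights = {
                k.split("::", 1)[1]: archive[k]
                for k in archive.files
                if k.startswith("weight::")
            }
            net = AgeNet(
                n_channels=est.n_channels_,
                fb_mask=mask,
                hidden_size=est.hidden_size,
                n_gru_layers=est.n_gru_layers,
            )
            net.set_parameters(weights)
            est.net_ = net
            est.filterbank_ = TriangularFilterbank(
                mask=mask,
                weights=net.fb_W,
                boundary_bins=archive["fb_boundaries"],
                freqs_hz=est.freqs_hz_,
            )
            est.n_features_in_ = est.n_channels_ * mask.shape[0]
        return est
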