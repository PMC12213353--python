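"""Dataset splitting, per-epoch MAE bookkeeping, and the model-selection rule.

An epoch is selected by its ``meanMAE`` — the average of training-set and
validation-set MAE — subject to ``deltaMAE`` (their absolute difference)
staying small: among epochs with ``deltaMAE <= tolerance`` the one with the
lowest ``meanMAE`` wins; if no epoch qualifies, the global ``meanMAE``
minimum is returned with a warning. Low meanMAE alone can hide overfitting;
the delta term guards train/validation consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EpochRecord:
    """One epoch of training: optimized loss plus train/validation MAE (years)."""

    epoch: int
    loss: float
    mae_train: float
    mae_validate: float

    @property
    def mean_mae(self) -> float:
        return 0.5 * (self.mae_train + self.mae_validate)

    @property
    def delta_mae(self) -> float:
        return abs(self.mae_train - self.mae_validate)


@dataclass
class TrainingHistory:
    """Consecutive per-epoch records with meanMAE/deltaMAE derived columns."""

    records: list[EpochRecord] = field(default_factory=list)

    def append(self, record: EpochRecord) -> None:
        expected = self.records[-1].epoch + 1 if self.records else 1
        if record.epoch != expected:
            raise ValueError(f"epoch {record.epoch} out of sequence (expected {expected})")
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": [r.epoch for r in self.records],
                "loss": [r.loss for r in self.records],
                "mae_train": [r.mae_train for r in self.records],
                "mae_validate": [r.mae_validate for r in self.records],
                "mean_mae": [r.mean_mae for r in self.records],
                "delta_mae": [r.delta_mae for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrainingHistory":
        hist = cls()
        for row in df.itertuples():
            hist.append(EpochRecord(int(row.epoch), float(row.loss),
                                    float(row.mae_train), float(row.mae_validate)))
        return hist


def select_model(history: TrainingHistory, delta_tolerance_years: float = 0.5) -> int:
    """Epoch number of the preferred model under the meanMAE/deltaMAE rule.

    Ties resolve to the earliest epoch. Returns a 1-based epoch number.
    """
    if not history.records:
        raise ValueError("cannot select from an empty history")
    eligible = [r for r in history.records if r.delta_mae <= delta_tolerance_years]
    if not eligible:
        warnings.warn(
            f"no epoch has deltaMAE <= {delta_tolerance_years}; "
            "falling back to the global meanMAE minimum",
            stacklevel=2,
        )
        eligible = history.records
    best = min(eligible, key=lambda r: (r.mean_mae, r.epoch))
    return best.epoch


@dataclass
class DatasetSplit:
    """Disjoint train/validate/test recording-id lists covering the input."""

    train: list
    validate: list
    test: list
    ratios: tuple[float, float, float]
    seed: int

    def subsets(self) -> dict[str, list]:
        return {"train": self.train, "validate": self.validate, "test": self.test}


def _proportional_counts(group_sizes: list[int], total_pick: int) -> list[int]:
    """Largest-remainder allocation of ``total_pick`` draws across groups."""
    sizes = np.asarray(group_sizes, dtype=float)
    if total_pick == 0 or sizes.sum() == 0:
        return [0] * len(group_sizes)
    quota = sizes / sizes.sum() * total_pick
    counts = np.floor(quota).astype(int)
    remainder = total_pick - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return [int(min(c, s)) for c, s in zip(counts, group_sizes)]


def split_dataset(
    recording_ids,
    ratios: tuple[float, float, float] = (8.0, 1.0, 1.0),
    seed: int = 0,
    ages=None,
    n_strata: int = 10,
) -> DatasetSplit:
    """Seeded random 8:1:1 partition of recordings, optionally age-stratified.

    Validation and test sizes are ``floor(n * ratio)``; the remainder goes to
    the training set, so 10 recordings split 8/1/1 and 772 split 618/77/77.
    With ``ages`` given, recordings are binned into ``n_strata`` age bins and
    validation/test draws are spread proportionally across bins (largest
    remainder), mirroring the stratified allocation of the study design.
    """
    ids = list(recording_ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 recordings to form 3 subsets, got {n}")
    total = float(sum(ratios))
    n_val = max(1, int(n * ratios[1] / total)) if ratios[1] > 0 else 0
    n_test = max(1, int(n * ratios[2] / total)) if ratios[2] > 0 else 0
    if n - n_val - n_test < 1:
        raise ValueError(f"{n} recordings cannot populate all three subsets")
    rng = np.random.default_rng(seed)

    if ages is None:
        order = rng.permutation(n)
        val_idx = set(order[:n_val].tolist())
        test_idx = set(order[n_val:n_val + n_test].tolist())
    else:
        ages = np.asarray(ages, dtype=float)
        if ages.size != n:
            raise ValueError("ages must match recording_ids in length")
        n_bins = min(n_strata, n)
        by_age = np.argsort(ages, kind="stable")
        bins = np.array_split(by_age, n_bins)
        per_bin_val = _proportional_counts([len(b) for b in bins], n_val)
        # test quotas come from the capacity left after validation draws
        per_bin_test = _proportional_counts(
            [len(b) - v for b, v in zip(bins, per_bin_val)], n_test
        )
        val_idx, test_idx = set(), set()
        for b, nv, nt in zip(bins, per_bin_val, per_bin_test):
            picked = rng.permutation(b)
            val_idx.update(picked[:nv].tolist())
            test_idx.update(picked[nv:nv + nt].tolist())

    train, validate, test = [], [], []
    for i, rid in enumerate(ids):
        if i in val_idx:
            validate.append(rid)
        elif i in test_idx:
            test.append(rid)
        else:
            train.append(rid)
    return DatasetSplit(train=train, validate=validate, test=test,
                        ratios=tuple(ratios), seed=seed)


def split_by_subject(
    recording_ids, subject_ids, ratios=(8.0, 1.0, 1.0), seed: int = 0, ages=None
) -> DatasetSplit:
    """Subject-level split: all recordings of one subject land in one subset.

    Recommended when subjects have repeat recordings; the plain
    recording-level split can let one child's recordings straddle subsets.
    """
    subj_to_recs: dict = {}
    subj_age: dict = {}
    for i, (rid, sid) in enumerate(zip(recording_ids, subject_ids)):
        subj_to_recs.setdefault(sid, []).append(rid)
        if ages is not None:
            subj_age.setdefault(sid, float(np.asarray(ages)[i]))
    subjects = list(subj_to_recs)
    subj_split = split_dataset(
        subjects, ratios, seed,
        ages=[subj_age[s] for s in subjects] if ages is not None else None,
    )
    def expand(sids):
        return [rid for s in sids for rid in subj_to_recs[s]]
    return DatasetSplit(
        train=expand(subj_split.train),
        validate=expand(subj_split.validate),
        test=expand(subj_split.test),
        ratios=tuple(ratios),
        seed=seed,
    )


def train_model(
    train_graphs,
    train_ages,
    val_graphs,
    val_ages,
    *,
    epochs: int = 50,
    lr: float = 1e-3,
    batch_size: int = 64,
    n_filters: int = 32,
    hidden_size: int = 64,
    n_gru_layers: int = 2,
    loss: str = "mae",
    delta_tolerance_years: float = 0.5,
    seed: int = 0,
):
    """Fit a :class:`~eegage.model.BrainAgeRegressor` on explicit train/validation sets.

    Returns ``(estimator, history)``; the estimator holds the weights of the
    epoch chosen by :func:`select_model`.
    """
    from .model import BrainAgeRegressor  # local import avoids a cycle

    if len(train_ages) == 0 or len(val_ages) == 0:
        raise ValueError("train and validation sets must be non-empty")
    est = BrainAgeRegressor(
        n_filters=n_filters,
        hidden_size=hidden_size,
        n_gru_layers=n_gru_layers,
        epochs=epochs,
        lr=lr,
        batch_size=batch_size,
        loss=loss,
        delta_tolerance_years=delta_tolerance_years,
        random_state=seed,
    )
    est.fit(train_graphs, train_ages, validation_data=(val_graphs, val_ages))
    return est, est.history_
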