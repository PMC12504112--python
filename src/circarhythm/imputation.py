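"""Imputation of missing slot values: an LSTM sequence model plus
deterministic baselines.

The sequence model predicts the next slot value from the six preceding
consecutive observed slots (2-h grid, windows never spanning a missing slot
or a grid gap).  Training pairs are split between participants — never within
a participant — so evaluation reflects imputation for unseen individuals.
Values are min-max scaled to [0, 1] using bounds learned from the training
split only.  At inference, missing slots are filled autoregressively in
chronological order, using previously imputed values as history; a missing
slot with fewer than six consecutive preceding values stays missing and is
counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lstm import LSTMRegressor

SLOT_STEP = pd.Timedelta(hours=2)

__all__ = [
    "ImputerHyperparams",
    "ImputerModel",
    "ImputationReport",
    "build_sequences",
    "user_level_split",
    "train_imputer",
    "impute",
    "baseline_impute",
]


@dataclass(frozen=True)
class ImputerHyperparams:
    units: int = 50
    dense_units: int = 25
    seq_len: int = 6
    epochs: int = 100
    batch_size: int = 5
    train_fraction: float = 0.8
    val_fraction: float = 0.1
    patience: int = 10
    learning_rate: float = 5e-3


@dataclass
class ImputerModel:
    """Trained sequence imputer with its scaling bounds (train data only)."""

    net: LSTMRegressor
    metric: str
    seq_len: int
    x_min: float
    x_max: float
    hyperparams: ImputerHyperparams = field(default_factory=ImputerHyperparams)

    @property
    def _scale_range(self) -> float:
        return (self.x_max - self.x_min) or 1.0

    def scale(self, values):
        return (np.asarray(values, dtype=float) - self.x_min) / self._scale_range

    def unscale(self, values):
        return np.asarray(values, dtype=float) * self._scale_range + self.x_min

    def predict(self, windows) -> np.ndarray:
        """Predict next-slot values from (n, seq_len) raw-unit windows."""
        windows = np.atleast_2d(np.asarray(windows, dtype=float))
        if windows.shape[1] != self.seq_len:
            raise ValueError(f"windows must have length {self.seq_len}")
        return self.unscale(self.net.predict(self.scale(windows)))


@dataclass(frozen=True)
class ImputationReport:
    n_missing_before: int
    n_imputed: int
    n_unimputable: int

    @property
    def fraction_unimputed(self) -> float:
        if self.n_missing_before == 0:
            return 0.0
        return self.n_unimputable / self.n_missing_before


def build_sequences(samples: pd.DataFrame, seq_len: int = 6) -> pd.DataFrame:
    """Extract (window, target) training pairs from observed slot runs.

    One pair per window of ``seq_len + 1`` consecutive observed slots within a
    participant's timeline (per metric); consecutive means exactly 2 h apart,
    which continues across midnight when adjacent days were both recorded.
    Returns a DataFrame with columns ``participant_id, metric,
    target_timestamp, x0..x{seq_len-1}, y``.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    rows = []
    for (pid, metric), sub in samples.groupby(["participant_id", "metric"], sort=False):
        sub = sub.sort_values("timestamp")
        ts = sub["timestamp"].to_numpy()
        vals = sub["value"].to_numpy(dtype=float)
        observed = np.isfinite(vals)
        consecutive = np.concatenate(
            [[False], (ts[1:] - ts[:-1]) == SLOT_STEP.to_numpy()]
        )
        # run-break before index i when i is unobserved or not 2h after i-1
        for start, stop in _runs(observed, consecutive):
            for w0 in range(start, stop - seq_len):
                rows.append(
                    (pid, metric, ts[w0 + seq_len], *vals[w0:w0 + seq_len], vals[w0 + seq_len])
                )
    cols = ["participant_id", "metric", "target_timestamp"] + [f"x{i}" for i in range(seq_len)] + ["y"]
    return pd.DataFrame(rows, columns=cols)


def _runs(observed: np.ndarray, consecutive: np.ndarray):
    """Yield (start, stop) half-open index ranges of consecutive observed slots."""
    n = observed.size
    i = 0
    while i < n:
        if not observed[i]:
            i += 1
            continue
        j = i + 1
        while j < n and observed[j] and consecutive[j]:
            j += 1
        yield i, j
        i = j


def pair_matrix(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a pair table into (X, y) numpy arrays."""
    xcols = [c for c in pairs.columns if c.startswith("x")]
    return pairs[xcols].to_numpy(dtype=float), pairs["y"].to_numpy(dtype=float)


def user_level_split(
    pairs: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition pairs by participant: round(train_fraction * n) participants
    (half-up, clamped so both sides are non-empty) go to training."""
    participants = sorted(pairs["participant_id"].unique())
    n = len(participants)
    if n < 2:
        raise ValueError("user-level split requires at least 2 participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    train_ids = {participants[i] for i in order[:n_train]}
    in_train = pairs["participant_id"].isin(train_ids)
    return pairs[in_train].reset_index(drop=True), pairs[~in_train].reset_index(drop=True)


def train_imputer(
    train_pairs: pd.DataFrame,
    hyperparams: ImputerHyperparams | None = None,
    seed: int = 0,
) -> ImputerModel:
    """Train the LSTM imputer on one metric's training pairs.

    Scaling bounds come from the training pairs only.  A validation slice
    (user-level when there are enough participants, otherwise the tail of the
    shuffled pairs) drives early stopping with best-weight restoration.
    """
    hp = hyperparams or ImputerHyperparams()
    if train_pairs.empty:
        raise ValueError("empty training set")
    metrics = train_pairs["metric"].unique()
    if len(metrics) != 1:
        raise ValueError("train one imputer per metric")
    metric = metrics[0]
    X, y = pair_matrix(train_pairs)
    if X.shape[1] != hp.seq_len:
        raise ValueError(f"pairs have window length {X.shape[1]}, expected {hp.seq_len}")

    n_participants = train_pairs["participant_id"].nunique()
    if hp.val_fraction > 0 and n_participants >= 3:
        fit_pairs, val_pairs = user_level_split(train_pairs, 1.0 - hp.val_fraction, seed=seed + 1)
        X_fit, y_fit = pair_matrix(fit_pairs)
        X_val, y_val = pair_matrix(val_pairs)
    elif hp.val_fraction > 0 and len(train_pairs) >= 10:
        rng = np.random.default_rng(seed + 1)
        order = rng.permutation(len(train_pairs))
        n_val = max(1, int(hp.val_fraction * len(train_pairs)))
        X_fit, y_fit = X[order[n_val:]], y[order[n_val:]]
        X_val, y_val = X[order[:n_val]], y[order[:n_val]]
    else:
        X_fit, y_fit, X_val, y_val = X, y, None, None

    x_min = float(min(X_fit.min(), y_fit.min()))
    x_max = float(max(X_fit.max(), y_fit.max()))
    span = (x_max - x_min) or 1.0
    scale = lambda a: (np.asarray(a, dtype=float) - x_min) / span  # noqa: E731

    net = LSTMRegressor(hp.units, hp.dense_units, hp.learning_rate, rng=seed)
    net.fit(
        scale(X_fit),
        scale(y_fit),
        scale(X_val) if X_val is not None else None,
        scale(y_val) if y_val is not None else None,
        epochs=hp.epochs,
        batch_size=hp.batch_size,
        patience=hp.patience,
    )
    return ImputerModel(net=net, metric=metric, seq_len=hp.seq_len,
                        x_min=x_min, x_max=x_max, hyperparams=hp)


def impute(model: ImputerModel, samples: pd.DataFrame) -> tuple[pd.DataFrame, ImputationReport]:
    """Fill missing slots of ``model.metric`` autoregressively.

    Missing slots with >= seq_len preceding consecutive observed-or-imputed
    slots are filled in chronological order; observed values are never
    altered.  Adds a boolean ``imputed`` column.
    """
    out = samples.copy()
    if "imputed" not in out.columns:
        out["imputed"] = False
    mask_metric = out["metric"] == model.metric
    n_missing = int(out.loc[mask_metric, "value"].isna().sum())
    n_imputed = 0
    L = model.seq_len
    step = SLOT_STEP.to_numpy()
    for pid, idx in out.index[mask_metric].groupby(out.loc[mask_metric, "participant_id"]).items():
        sub = out.loc[idx].sort_values("timestamp")
        ts = sub["timestamp"].to_numpy()
        vals = sub["value"].to_numpy(dtype=float)
        order = sub.index.to_numpy()
        for i in range(L, len(vals)):
            if np.isfinite(vals[i]):
                continue
            window = vals[i - L:i]
            if not np.all(np.isfinite(window)):
                continue
            if not np.all((ts[i - L + 1:i + 1] - ts[i - L:i]) == step):
                continue
            pred = float(model.predict(window[None, :])[0])
            vals[i] = pred
            out.loc[order[i], "value"] = pred
            out.loc[order[i], "imputed"] = True
            n_imputed += 1
    return out, ImputationReport(
        n_missing_before=n_missing,
        n_imputed=n_imputed,
        n_unimputable=n_missing - n_imputed,
    )


def baseline_impute(samples: pd.DataFrame, method: str = "linear_interp") -> pd.DataFrame:
    """Deterministic imputation baselines.

    ``slot_mean`` fills a missing slot with the participant's mean observed
    value at that slot hour (falling back to the participant's overall mean);
    ``linear_interp`` interpolates linearly over slot hours within each day,
    holding the nearest observed value at day edges.  Observed values are
    untouched; an ``imputed`` flag column is added.
    """
    if method not in ("slot_mean", "linear_interp"):
        raise ValueError(f"unknown baseline method {method!r}")
    out = samples.copy()
    if "imputed" not in out.columns:
        out["imputed"] = False
    missing_before = out["value"].isna()
    if method == "slot_mean":
        grp = out.groupby(["participant_id", "metric", "slot_hour"])["value"]
        slot_means = grp.transform("mean")
        overall = out.groupby(["participant_id", "metric"])["value"].transform("mean")
        fill = slot_means.fillna(overall)
        out["value"] = out["value"].fillna(fill)
    else:
        date = out["timestamp"].dt.date
        for _, idx in out.groupby([out["participant_id"], date, out["metric"]]).groups.items():
            sub = out.loc[idx].sort_values("slot_hour")
            vals = sub["value"].to_numpy(dtype=float)
            obs = np.isfinite(vals)
            if obs.all() or not obs.any():
                continue
            hours = sub["slot_hour"].to_numpy(dtype=float)
            filled = np.interp(hours, hours[obs], vals[obs])
            out.loc[sub.index, "value"] = filled
    out["imputed"] = out["imputed"] | (missing_before & out["value"].notna())
    return out
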