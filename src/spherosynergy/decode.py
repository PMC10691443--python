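"""Viability decoding: train on endpoint-labeled images, predict all days.

The screen's lysing endpoint assay yields one viability label per well on
the final day only.  This module trains the dense-connectivity CNN
(:mod:`spherosynergy.nn`) to regress % viability from the preprocessed
endpoint images, then applies the frozen model to every imaging day.  Raw
per-image predictions are re-normalized per plate and day against the
untreated control well (100 %), which absorbs the day-to-day drift in
spheroid size that the endpoint-only training cannot see.

Data hygiene is by drug pair: all images of a pair belong either to the
train+validation pool or to the held-out test pool, never both, so the
evaluation measures generalization to unseen combinations rather than
memorization of a plate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import nn

__all__ = [
    "SplitSpec",
    "NetConfig",
    "FitMetrics",
    "ImageSet",
    "split_dataset",
    "train_model",
    "predict_viability",
    "normalize_per_day",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class SplitSpec:
    """Pair-level train/test split plus within-train validation fraction.

    ``train_pairs`` lists pair names assigned to the train+validation pool;
    every other pair goes to the test pool.  The 70/30 train/validation
    split happens *within* the pool, by well, with ``split_seed``.
    """

    train_pairs: tuple[str, ...]
    val_fraction: float = 0.30
    split_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.val_fraction < 1):
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass(frozen=True)
class NetConfig:
    """Decoder hyperparameters; see :class:`~spherosynergy.nn.DenseNetRegressor`."""

    input_size: int = 128
    stem_channels: int = 8
    block_layers: tuple[int, ...] = (2, 2)
    growth: int = 8
    compression: float = 0.5
    hidden: int = 16
    epochs: int = 150
    batch_size: int = 32
    learning_rate: float = 3e-3
    patience: int = 40
    train_seed: int = 0


@dataclass(frozen=True)
class FitMetrics:
    """OLS agreement between observed and predicted values.

    ``adj_r_squared`` is the coefficient of determination of the
    observed-on-predicted regression, penalized for the two fitted
    coefficients: ``1 - (1 - R^2) (n-1)/(n-2)``.
    """

    adj_r_squared: float
    r_squared: float
    p_value: float
    n: int
    slope: float
    intercept: float


@dataclass
class ImageSet:
    """Aligned images + metadata; the in-memory dataset all stages share."""

    images: np.ndarray  # (n, s, s) floats in [0, 1]
    meta: pd.DataFrame  # one row per image; 'pair' column required for splits

    def __post_init__(self) -> None:
        if len(self.images) != len(self.meta):
            raise ValueError("images and metadata length mismatch")
        self.meta = self.meta.reset_index(drop=True)

    def subset(self, mask: np.ndarray | pd.Series) -> "ImageSet":
        mask = np.asarray(mask)
        return ImageSet(self.images[mask], self.meta.loc[mask])

    def __len__(self) -> int:
        return len(self.meta)


def split_dataset(
    data: ImageSet, spec: SplitSpec
) -> tuple[ImageSet, ImageSet, ImageSet]:
    """Split into (train, validation, test) with pair-level hygiene.

    Records whose ``pair`` is in ``spec.train_pairs`` (plus any empty-well
    reference records, tagged pair == 'empty') form the train+validation
    pool; the rest are the test set.  The pool is then split by a seeded
    shuffle into ``1 - val_fraction`` train / ``val_fraction`` validation.
    """
    pairs = set(data.meta["pair"])
    train_pairs = set(spec.train_pairs)
    unknown = train_pairs - pairs
    if unknown:
        raise ValueError(f"train_pairs not present in data: {sorted(unknown)}")
    test_pairs = pairs - train_pairs - {"empty"}
    overlap = train_pairs & test_pairs
    if overlap:
        raise ValueError(f"pairs assigned to both sets: {sorted(overlap)}")

    in_pool = data.meta["pair"].isin(train_pairs | {"empty"}).to_numpy()
    pool_idx = np.flatnonzero(in_pool)
    rng = np.random.default_rng(spec.split_seed)
    shuffled = rng.permutation(pool_idx)
    n_val = int(round(spec.val_fraction * len(shuffled)))
    val_idx = np.sort(shuffled[:n_val])
    train_idx = np.sort(shuffled[n_val:])
    test_idx = np.flatnonzero(~in_pool)

    pick = lambda idx: ImageSet(data.images[idx], data.meta.loc[idx])
    return pick(train_idx), pick(val_idx), pick(test_idx)


def train_model(
    train: ImageSet,
    val: ImageSet,
    cfg: NetConfig | None = None,
    label_column: str = "viability_pct",
) -> tuple[nn.DenseNetRegressor, pd.DataFrame]:
    """Fit the decoder on labeled images, minimizing mean squared error.

    Returns the model with its best-validation-MSE weights restored and the
    per-epoch loss history.  Deterministic given ``cfg.train_seed``.
    """
    cfg = cfg or NetConfig()
    if len(train) == 0:
        raise ValueError("empty training set")
    for name, ds in (("train", train), ("validation", val)):
        if len(ds) and ds.meta[label_column].isna().any():
            raise ValueError(f"{name} set contains unlabeled images")
    model = nn.DenseNetRegressor(
        input_size=cfg.input_size,
        stem_channels=cfg.stem_channels,
        block_layers=cfg.block_layers,
        growth=cfg.growth,
        compression=cfg.compression,
        hidden=cfg.hidden,
        seed=cfg.train_seed,
    )
    history = nn.train_regressor(
        model,
        train.images,
        train.meta[label_column].to_numpy(float),
        val.images if len(val) else None,
        val.meta[label_column].to_numpy(float) if len(val) else None,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        lr=cfg.learning_rate,
        patience=cfg.patience,
        seed=cfg.train_seed,
    )
    hist_df = pd.DataFrame(
        {"epoch": history.epoch, "train_mse": history.train_mse,
         "val_mse": history.val_mse}
    )
    return model, hist_df


def predict_viability(model: nn.DenseNetRegressor, images: np.ndarray) -> np.ndarray:
    """Raw decoder output in % viability, one finite value per image.

    No clipping or normalization happens here; :func:`normalize_per_day`
    owns the per-plate, per-day rescaling.
    """
    images = np.asarray(images, dtype=float)
    if len(images) == 0:
        return np.empty(0)
    preds = model.predict(images)
    if not np.all(np.isfinite(preds)):
        raise FloatingPointError("non-finite prediction encountered")
    return preds


def normalize_per_day(predictions: pd.DataFrame) -> pd.DataFrame:
    """Rescale raw predictions so each plate-day's untreated well reads 100 %.

    ``predictions`` needs columns ``plate_id, day, row, col, raw_pred``.
    Output adds ``viability_pct`` (scaled, floored at 0; the untreated well
    itself exactly 100) and a boolean ``missing`` flag: if a (plate, day)
    group lacks its untreated well or its raw prediction is non-positive,
    the whole group is flagged rather than silently scaled.
    """
    required = {"plate_id", "day", "row", "col", "raw_pred"}
    if not required <= set(predictions.columns):
        raise ValueError(f"missing columns: {sorted(required - set(predictions.columns))}")
    out = predictions.copy().reset_index(drop=True)
    out["viability_pct"] = np.nan
    out["missing"] = False
    for (_, _), grp in out.groupby(["plate_id", "day"], sort=False):
        anchor = grp[(grp["row"] == 0) & (grp["col"] == 0)]
        if len(anchor) != 1 or anchor["raw_pred"].iloc[0] <= 0:
            out.loc[grp.index, "missing"] = True
            continue
        ref = float(anchor["raw_pred"].iloc[0])
        scaled = np.maximum(grp["raw_pred"].to_numpy(float) * 100.0 / ref, 0.0)
        out.loc[grp.index, "viability_pct"] = scaled
        out.loc[anchor.index, "viability_pct"] = 100.0
    return out


def evaluate_predictions(
    pred: Sequence[float], obs: Sequence[float]
) -> FitMetrics:
    """OLS of observed on predicted with adjusted R² and slope p-value.

    Callers merging technical replicates should average them before calling
    (the replicate-mean rule); this function treats each pair of values as
    one sample.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be 1-D and aligned")
    keep = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[keep], obs[keep]
    n = len(pred)
    if n < 3:
        raise ValueError(f"need at least 3 finite pairs, got {n}")
    if np.ptp(pred) == 0:
        raise ZeroDivisionError("zero variance in predictions: fit undefined")
    fit = stats.linregress(pred, obs)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return FitMetrics(
        adj_r_squared=float(adj),
        r_squared=float(r2),
        p_value=float(fit.pvalue),
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
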