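"""Sample validation, label encoding, min–max normalization and splitting.

The preprocessing chain mirrors the garment pipeline: raw frames are checked
for validity (non-finite or out-of-range channel values are dropped), the
acquired posture types are encoded to the seven numeric classification
labels (merging the left/right leg-crossed sub-variants), the four channels
are min–max rescaled to [0, 1] using training-partition extrema, and the
table is split 80/20 (stratified) into training and test partitions.

Normalization granularity: the default fits one scaler per channel on the
whole training partition; ``minmax_normalize_per_participant`` additionally
offers per-participant rescaling, which exactly removes the multiplicative
participant amplitude factor the simulator injects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import MinMaxScaler

from .postures import CHANNELS, AcquiredPosture, Posture, posture_from_name
from .simulate import SimConfig


@dataclass
class Dataset:
    """A labelled feature table: n×4 channel matrix plus label codes."""

    features: np.ndarray
    labels: np.ndarray
    normalized: bool = False
    scaler_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[1] != len(CHANNELS):
            raise ValueError("features must be an n×4 matrix")
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_frame_table(cls, df: pd.DataFrame) -> "Dataset":
        return cls(df[list(CHANNELS)].to_numpy(float), encode_labels(df))


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters (default: stratified 80/20)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def default_validity_bounds(config: SimConfig) -> dict[str, tuple[float, float]]:
    """Per-channel validity bounds: the simulator's signal range ±50%.

    The signal range is the class-mean range extended by 4 noise SDs on each
    side (covering essentially all regular frames), then padded by half its
    own width; anything outside is treated as a sensor fault.
    """
    means = np.vstack([config.mean_matrix(), np.asarray(config.other_modes, float)])
    tail = 4.0 * config.noise_sd * max(config.noise_scale.values())
    lo, hi = means.min(axis=0) - tail, means.max(axis=0) + tail
    pad = 0.5 * (hi - lo)
    return {c: (float(l - p), float(h + p)) for c, l, h, p in zip(CHANNELS, lo, hi, pad)}


def validate_samples(
    frames: pd.DataFrame, bounds: Mapping[str, tuple[float, float]]
) -> tuple[pd.DataFrame, int]:
    """Drop frames with any non-finite or out-of-bounds channel value.

    Returns the kept frames (original order preserved) and the dropped count.
    """
    for c in CHANNELS:
        lo, hi = bounds[c]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds for {c} must be finite with lo < hi")
    if frames.empty:
        return frames.copy(), 0
    values = frames[list(CHANNELS)].to_numpy(float)
    lo = np.array([bounds[c][0] for c in CHANNELS])
    hi = np.array([bounds[c][1] for c in CHANNELS])
    ok = np.isfinite(values).all(axis=1)
    ok &= ((values >= lo) & (values <= hi)).all(axis=1)
    kept = frames.loc[ok].copy()
    return kept, int((~ok).sum())


def encode_labels(frames: pd.DataFrame | Iterable) -> np.ndarray:
    """Encode acquired postures to the seven numeric classification labels.

    Both leg-crossed sub-variants collapse onto code 3; the code set follows
    the fixed legend (0 stance, 1 upright, 2 back bent, 3 leg crossed,
    4 forward, 5 backward, 6 other). Accepts a frame table (``posture_code``
    column or ``posture`` name column) or a sequence of ``AcquiredPosture`` /
    posture names.
    """
    if isinstance(frames, pd.DataFrame):
        if "posture_code" in frames.columns:
            codes = frames["posture_code"].to_numpy(int)
            if codes.size and (codes.min() < 0 or codes.max() > 6):
                bad = codes[(codes < 0) | (codes > 6)][0]
                raise ValueError(f"unknown posture code: {bad}")
            return codes
        if "posture" in frames.columns:
            return np.array(
                [int(posture_from_name(n)) for n in frames["posture"]], dtype=int
            )
        raise ValueError("frame table has neither posture_code nor posture column")
    out = []
    for item in frames:
        if isinstance(item, AcquiredPosture):
            out.append(int(item.label))
        elif isinstance(item, Posture):
            out.append(int(item))
        else:
            out.append(int(posture_from_name(item)))
    return np.array(out, dtype=int)


def minmax_normalize(
    train: Dataset, others: Sequence[Dataset] = ()
) -> tuple[Dataset, list[Dataset], dict[str, tuple[float, float]]]:
    """Min–max rescale channels to [0, 1] using training-partition extrema.

    The scaler is fitted on ``train`` only and applied unchanged to
    ``others`` (values outside the training range map outside [0, 1]; no
    clipping, so the transform stays affine and invertible). A constant
    channel maps to 0 everywhere.
    """
    if len(train) == 0:
        raise ValueError("training partition must be non-empty")
    scaler = MinMaxScaler().fit(train.features)
    params = {
        c: (float(lo), float(hi))
        for c, lo, hi in zip(CHANNELS, scaler.data_min_, scaler.data_max_)
    }
    # transform via the direct quotient: (x - min)/(max - min) is exact at the
    # training extrema, where scaler.transform's x*scale + shift can overshoot
    # [0, 1] by an ulp
    train_n = Dataset(
        apply_scaler_params(train.features, params), train.labels, True, params
    )
    others_n = [
        Dataset(apply_scaler_params(d.features, params), d.labels, True, params)
        for d in others
    ]
    return train_n, others_n, params


def apply_scaler_params(
    features: np.ndarray, params: Mapping[str, tuple[float, float]]
) -> np.ndarray:
    """Apply persisted per-channel (min, max) parameters to a feature matrix."""
    lo = np.array([params[c][0] for c in CHANNELS])
    hi = np.array([params[c][1] for c in CHANNELS])
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    return (np.asarray(features, float) - lo) / span


def minmax_normalize_per_participant(frames: pd.DataFrame) -> pd.DataFrame:
    """Rescale each channel to [0, 1] within each participant's own session.

    Removes participant-level amplitude differences exactly when they are
    multiplicative, at the cost of needing each participant's full session
    before classification.
    """
    out = frames.copy()
    for _, idx in frames.groupby("participant").groups.items():
        block = frames.loc[idx, list(CHANNELS)].to_numpy(float)
        lo, hi = block.min(axis=0), block.max(axis=0)
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        out.loc[idx, list(CHANNELS)] = (block - lo) / span
    return out


def split(dataset: Dataset, spec: SplitSpec = SplitSpec()) -> tuple[Dataset, Dataset]:
    """Partition a dataset into disjoint, exhaustive train/test subsets."""
    if spec.stratified:
        counts = np.bincount(dataset.labels)
        if (counts[counts > 0] < 2).any():
            raise ValueError("stratified split needs >= 2 members per class")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=dataset.labels if spec.stratified else None,
    )
    sub = lambda i: Dataset(
        dataset.features[i], dataset.labels[i], dataset.normalized, dataset.scaler_params
    )
    return sub(np.sort(train_idx)), sub(np.sort(test_idx))
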