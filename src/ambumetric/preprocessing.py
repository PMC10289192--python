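"""Missing-value interpolation, daily aggregation, and normalization.

Feature normalization is min-max anchored to the training participants;
held-out values falling outside the trained range are clipped to [0, 1].
Labels are L2-normalized per participant over that participant's training
labels (pairs are formed strictly within participant, so only
same-participant normalized labels are ever compared).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema_io import DAY_COL, ID_COL, Dataset

__all__ = ["NormalizationStats", "LabelNormalizer", "interpolate_missing",
           "interpolate_dataset", "daily_average", "fit_minmax",
           "apply_minmax", "fit_label_normalizers", "normalize_labels"]


class PreprocessingError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationStats:
    feature_min: pd.Series
    feature_max: pd.Series
    fitted_on: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.feature_min > self.feature_max).any():
            raise PreprocessingError("per-feature min must be <= max")


@dataclass(frozen=True)
class LabelNormalizer:
    """Per-participant L2 norms of training labels."""

    norms: dict[str, float]

    def __call__(self, participant_id: str, y: np.ndarray) -> np.ndarray:
        norm = self.norms.get(str(participant_id))
        if norm is None:
            raise KeyError(f"no label norm for participant "
                           f"{participant_id!r}")
        return np.asarray(y, float) / norm


def interpolate_missing(series: "pd.Series | np.ndarray") -> pd.Series:
    """Fill gaps in an ordered series by linear interpolation.

    Interior gaps are interpolated between the nearest observed neighbors;
    leading/trailing gaps take the nearest observed value.
    """
    s = pd.Series(np.asarray(series, float))
    if s.notna().sum() == 0:
        raise PreprocessingError("cannot interpolate an all-missing series")
    return s.interpolate(method="linear", limit_direction="both")


def interpolate_dataset(dataset: Dataset) -> Dataset:
    """Interpolate every participant's feature series over day order."""
    frame = dataset.frame.sort_values([ID_COL, DAY_COL]).reset_index(
        drop=True)
    cols = dataset.feature_schema.names
    for pid, idx in frame.groupby(ID_COL, sort=False).groups.items():
        block = frame.loc[idx, cols]
        if block.notna().sum().eq(0).any():
            bad = block.columns[block.notna().sum() == 0][0]
            raise PreprocessingError(
                f"feature {bad!r} entirely missing for participant {pid!r}")
        frame.loc[idx, cols] = block.interpolate(
            method="linear", limit_direction="both")
    return dataset.replace_frame(frame)


def daily_average(frame: pd.DataFrame, feature_names: list[str],
                  label_names: list[str]) -> pd.DataFrame:
    """Collapse sub-daily rows to one row per participant-day.

    Features are averaged over the observed (non-missing) entries; label
    columns must be constant within a day and are carried through.
    """
    grouped = frame.groupby([ID_COL, DAY_COL], sort=True)
    for col in label_names:
        if col not in frame.columns:
            continue
        nun = grouped[col].nunique(dropna=True)
        if (nun > 1).any():
            key = nun[nun > 1].index[0]
            raise PreprocessingError(
                f"conflicting {col!r} labels within participant-day {key}")
    agg = {c: "mean" for c in feature_names}
    agg.update({c: "first" for c in label_names if c in frame.columns})
    other = [c for c in frame.columns
             if c not in agg and c not in (ID_COL, DAY_COL)]
    agg.update({c: "first" for c in other})
    return grouped.agg(agg).reset_index()


def fit_minmax(train: Dataset) -> NormalizationStats:
    """Per-feature min/max over the training participants' records."""
    if train.n_records == 0:
        raise PreprocessingError("cannot fit normalization on empty data")
    cols = train.feature_schema.names
    block = train.frame[cols]
    return NormalizationStats(feature_min=block.min(),
                              feature_max=block.max(),
                              fitted_on=tuple(train.participants))


def apply_minmax(dataset: Dataset, stats: NormalizationStats) -> Dataset:
    """Map each feature through (x - min) / (max - min), clipped to [0, 1].

    Constant features map to 0.
    """
    frame = dataset.frame.copy()
    cols = dataset.feature_schema.names
    span = (stats.feature_max - stats.feature_min).replace(0.0, np.nan)
    scaled = (frame[cols] - stats.feature_min) / span
    scaled = scaled.fillna(0.0).clip(0.0, 1.0)
    # re-blank cells that were missing before scaling
    scaled[frame[cols].isna()] = np.nan
    frame[cols] = scaled
    return dataset.replace_frame(frame)


def normalize_labels(train_labels: np.ndarray) -> float:
    """L2 norm of one participant's training label vector."""
    y = np.asarray(train_labels, float)
    y = y[~np.isnan(y)]
    if y.size == 0:
        raise PreprocessingError("participant has no training labels")
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        raise PreprocessingError("zero-norm training label vector")
    return norm


def fit_label_normalizers(train: Dataset, construct: str) -> LabelNormalizer:
    norms: dict[str, float] = {}
    frame = train.frame
    for pid, grp in frame.groupby(ID_COL, sort=False):
        labels = grp[construct].dropna().to_numpy(float)
        if labels.size == 0:
            continue
        norms[str(pid)] = normalize_labels(labels)
    if not norms:
        raise PreprocessingError(
            f"no participant has training labels for {construct!r}")
    return LabelNormalizer(norms=norms)
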