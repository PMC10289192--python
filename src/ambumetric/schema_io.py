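"""Cohort table schemas, CSV I/O, and the participant inclusion filter.

The data model is a wide daily table: one row per participant-day carrying
69 ambulatory feature columns (three device groups), 14 trait columns
(three trait groups, constant within participant), and up to four daily
construct label columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSchema",
    "TraitSchema",
    "LabelSchema",
    "ParticipantRecord",
    "Dataset",
    "SchemaError",
    "default_feature_schema",
    "default_trait_schema",
    "default_label_schemas",
    "CONSTRUCTS",
    "load_dataset",
    "save_dataset",
    "filter_participants",
]

ID_COL = "participant_id"
DAY_COL = "day_index"

CONSTRUCTS = ("anxiety", "stress", "positive_affect", "negative_affect")

_ACTIVITY_SLEEP = [
    "car_upper_threshold", "car_lower_threshold",
    "fbar_upper_threshold", "fbar_lower_threshold",
    "par_upper_threshold", "par_lower_threshold",
    "oorar_upper_threshold", "oorar_lower_threshold",
    "minutes_in_car", "minutes_in_fbar", "minutes_in_par", "minutes_in_oorar",
    "calories_in_car", "calories_in_fbar", "calories_in_par",
    "calories_in_oorar",
    "step_count",
    "minutes_awake", "minutes_deep_sleep", "minutes_light_sleep",
    "minutes_rem_sleep", "minutes_nonrem_sleep",
    "minutes_asleep", "minutes_in_bed", "sleep_efficiency",
]

_ACOUSTIC = [
    "jitter", "jitter_delta", "shimmer",
    "f0_mean", "f0_contour_mean", "f0_envelope_mean",
    "harmonic_noise_ratio", "voice_probability",
    "signal_norm", "rasta_plp_norm",
    "energy", "zero_crossing_rate", "intensity", "loudness",
    "fft_magnitude_250_650", "fft_magnitude_1000_4000",
    "rolloff_iqr_0_25", "rolloff_iqr_25_50",
    "rolloff_iqr_50_75", "rolloff_iqr_75_90",
    "spectral_flux", "spectral_centroid", "spectral_entropy",
    "spectral_variance", "spectral_skewness", "spectral_kurtosis",
    "spectral_slope", "spectral_sharpness", "spectral_harmonicity",
]

_PHYSIOLOGY = [
    "breathing_rate", "breathing_rate_variability",
    "heart_rate", "heart_rate_mean", "heart_rate_variability",
    "garment_intensity",
    "accel_x_mean", "accel_y_mean", "accel_z_mean",
    "rr_rmssd", "hrv_total_power", "hrv_vlf_power",
    "hrv_lf_power", "hrv_hf_power", "hrv_lf_hf_ratio",
]

_COGNITIVE = ["org_citizenship_behavior", "fluid_intelligence",
              "crystallized_intelligence"]
_PSYCHOLOGICAL = ["extraversion", "agreeableness", "conscientiousness",
                  "emotional_stability", "openness",
                  "trait_positive_affect", "trait_negative_affect",
                  "trait_anxiety"]
_HEALTH = ["tobacco_use", "tobacco_quantity", "sleep_quality"]


class SchemaError(ValueError):
    """Raised when a table violates its declared schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered ambulatory feature names grouped by recording device."""

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique across groups")

    @property
    def names(self) -> list[str]:
        return [n for g in self.groups.values() for n in g]

    @property
    def total_count(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class TraitSchema:
    """Ordered trait names grouped by instrument family, plus the
    construct-specific exclusion rule that prevents trait/label leakage."""

    groups: Mapping[str, tuple[str, ...]]
    leakage_exclusions: Mapping[str, tuple[str, ...]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise SchemaError("trait names must be unique across groups")
        for construct, dropped in self.leakage_exclusions.items():
            missing = set(dropped) - set(names)
            if missing:
                raise SchemaError(
                    f"leakage exclusion for {construct!r} names unknown "
                    f"traits: {sorted(missing)}")

    @property
    def names(self) -> list[str]:
        return [n for g in self.groups.values() for n in g]

    @property
    def total_count(self) -> int:
        return len(self.names)

    def names_for_construct(self, construct: str) -> list[str]:
        dropped = set(self.leakage_exclusions.get(construct, ()))
        return [n for n in self.names if n not in dropped]


@dataclass(frozen=True)
class LabelSchema:
    construct: str
    min_label: int
    max_label: int

    def __post_init__(self) -> None:
        if self.min_label > self.max_label:
            raise SchemaError("min_label must be <= max_label")

    def validate(self, values: pd.Series) -> None:
        present = values.dropna()
        bad = present[(present < self.min_label) | (present > self.max_label)]
        if len(bad):
            row = int(bad.index[0])
            raise SchemaError(
                f"label {self.construct!r} out of bounds "
                f"[{self.min_label}, {self.max_label}] at row {row}: "
                f"{bad.iloc[0]}")


def default_feature_schema() -> FeatureSchema:
    return FeatureSchema(groups={
        "activity_sleep": tuple(_ACTIVITY_SLEEP),
        "acoustic": tuple(_ACOUSTIC),
        "physiology": tuple(_PHYSIOLOGY),
    })


def default_trait_schema() -> TraitSchema:
    affect_traits = ("trait_positive_affect", "trait_negative_affect")
    return TraitSchema(
        groups={
            "cognitive": tuple(_COGNITIVE),
            "psychological": tuple(_PSYCHOLOGICAL),
            "health": tuple(_HEALTH),
        },
        leakage_exclusions={
            "positive_affect": affect_traits,
            "negative_affect": affect_traits,
        },
    )


def default_label_schemas() -> dict[str, LabelSchema]:
    return {
        "anxiety": LabelSchema("anxiety", 1, 5),
        "stress": LabelSchema("stress", 1, 5),
        "positive_affect": LabelSchema("positive_affect", 5, 25),
        "negative_affect": LabelSchema("negative_affect", 5, 24),
    }


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    day_index: int
    features: dict[str, float]
    traits: dict[str, float]
    labels: dict[str, float]


@dataclass
class Dataset:
    """A daily cohort table plus its schemas.

    ``frame`` is wide: participant id, day index, feature columns, trait
    columns, and one column per construct. (participant_id, day_index)
    pairs are unique.
    """

    frame: pd.DataFrame
    feature_schema: FeatureSchema
    trait_schema: TraitSchema
    label_schemas: dict[str, LabelSchema]

    def __post_init__(self) -> None:
        dup = self.frame.duplicated(subset=[ID_COL, DAY_COL])
        if dup.any():
            raise SchemaError(
                "duplicate (participant_id, day_index) rows at indices "
                f"{list(self.frame.index[dup][:5])}")

    # -- convenience accessors -------------------------------------------

    @property
    def participants(self) -> list[str]:
        return list(pd.unique(self.frame[ID_COL]))

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def feature_matrix(self) -> np.ndarray:
        return self.frame[self.feature_schema.names].to_numpy(float)

    def trait_table(self) -> pd.DataFrame:
        """One row per participant with that participant's trait vector."""
        cols = [ID_COL] + self.trait_schema.names
        tab = self.frame[cols].drop_duplicates(subset=ID_COL)
        if len(tab) != len(self.participants):
            raise SchemaError("traits vary within a participant")
        return tab.set_index(ID_COL)

    def labels(self, construct: str) -> pd.Series:
        return self.frame[construct]

    def subset(self, participant_ids: Sequence[str]) -> "Dataset":
        keep = self.frame[ID_COL].isin(set(participant_ids))
        return self.replace_frame(self.frame[keep].reset_index(drop=True))

    def replace_frame(self, frame: pd.DataFrame) -> "Dataset":
        return Dataset(frame, self.feature_schema, self.trait_schema,
                       self.label_schemas)

    def records(self) -> Iterator[ParticipantRecord]:
        fnames = self.feature_schema.names
        tnames = self.trait_schema.names
        for _, row in self.frame.iterrows():
            yield ParticipantRecord(
                participant_id=str(row[ID_COL]),
                day_index=int(row[DAY_COL]),
                features={n: row[n] for n in fnames},
                traits={n: row[n] for n in tnames},
                labels={c: row[c] for c in self.label_schemas
                        if c in row.index},
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.frame.reset_index(drop=True),
                other.frame.reset_index(drop=True),
                check_dtype=False)
        except AssertionError:
            return False
        return True


def load_dataset(path: str | Path,
                 feature_schema: FeatureSchema | None = None,
                 trait_schema: TraitSchema | None = None,
                 label_schemas: dict[str, LabelSchema] | None = None,
                 ) -> Dataset:
    """Read a wide daily CSV and validate it against the schemas.

    Missing values are empty cells. Unknown columns are reported via a
    warning; missing schema columns raise :class:`SchemaError`.
    """
    feature_schema = feature_schema or default_feature_schema()
    trait_schema = trait_schema or default_trait_schema()
    label_schemas = label_schemas or default_label_schemas()

    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc

    required = ([ID_COL, DAY_COL] + feature_schema.names
                + trait_schema.names)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing schema columns: {missing}")

    label_cols = [c for c in label_schemas if c in frame.columns]
    known = set(required) | set(label_schemas)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
        frame = frame.drop(columns=unknown)

    frame[ID_COL] = frame[ID_COL].astype(str)
    try:
        frame[DAY_COL] = frame[DAY_COL].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-integer {DAY_COL}: {exc}") from exc

    for col in feature_schema.names + trait_schema.names + label_cols:
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    for construct in label_cols:
        label_schemas[construct].validate(frame[construct])

    return Dataset(frame, feature_schema, trait_schema, label_schemas)


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the cohort as CSV (empty cells for missing values)."""
    dataset.frame.to_csv(path, index=False)


def filter_participants(dataset: Dataset, construct: str,
                        min_labeled_days: int = 13,
                        ) -> tuple[Dataset, int]:
    """Drop participants with fewer than ``min_labeled_days`` labeled days.

    Returns the filtered dataset and the number of dropped participants.
    """
    if min_labeled_days < 1:
        raise ValueError("min_labeled_days must be >= 1")
    if construct not in dataset.label_schemas:
        raise KeyError(f"unknown construct {construct!r}")
    counts = (dataset.frame[[ID_COL, construct]]
              .dropna(subset=[construct])
              .groupby(ID_COL, sort=False)
              .size())
    keep = counts[counts >= min_labeled_days].index
    n_dropped = len(dataset.participants) - len(keep)
    filtered = dataset.subset(list(keep))
    if filtered.n_records == 0:
        warnings.warn("no participants left after filtering", stacklevel=2)
    return filtered, n_dropped


# -- evaluation report serialization (round-trip JSON + CSV) --------------

def write_report(report: "EvalReport", path: str | Path) -> None:
    """Serialize an EvalReport as JSON; score table also as a CSV sibling."""
    from .evaluation import EvalReport  # local import: avoid cycle
    assert isinstance(report, EvalReport)
    path = Path(path)
    payload = report.to_dict()
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    report.scores.to_csv(path.with_suffix(".csv"), index=False)


def read_report(path: str | Path) -> "EvalReport":
    from .evaluation import EvalReport
    payload = json.loads(Path(path).read_text())
    return EvalReport.from_dict(payload)
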