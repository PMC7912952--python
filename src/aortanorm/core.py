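"""Domain types and anthropometric primitives.

Subjects carry demographics (age in years, sex), anthropometrics
(height in cm, weight in kg, body surface area in m²) and up to four
aortic diameters in mm, measured at the aortic annulus (AAn), sinuses
of Valsalva (SoV), sinotubular junction (SJ) and proximal ascending
aorta (PAA).

Height is handled in centimetres throughout: the Du Bois constant
0.007184 is the centimetre form of the formula, and typical adult
values (62 kg, 165 cm) then give the expected BSA of about 1.68 m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateScaleError,
    DomainError,
    IncompleteRecordError,
)

#: The four echocardiographic measurement levels of the proximal aorta,
#: in anatomical order from the valve outward.
LEVELS: tuple[str, ...] = ("AAn", "SoV", "SJ", "PAA")

#: Demographic/anthropometric feature names usable in feature specs.
DEMOGRAPHIC_FEATURES: tuple[str, ...] = ("age", "sex", "bsa")

_CSV_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "height_cm",
    "weight_kg",
    "aan_mm",
    "sov_mm",
    "sj_mm",
    "paa_mm",
    "group",
]

_LEVEL_TO_CSV = {"AAn": "aan_mm", "SoV": "sov_mm", "SJ": "sj_mm", "PAA": "paa_mm"}
_CSV_TO_LEVEL = {v: k for k, v in _LEVEL_TO_CSV.items()}

VALID_GROUPS = ("healthy", "dilated", "MFS", "BAV", "unknown")


def compute_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m²) by the Du Bois formula.

    BSA = 0.007184 · weight^0.425 · height^0.725, with weight in kg and
    height in cm.
    """
    if weight_kg <= 0:
        raise DomainError(f"weight_kg must be positive, got {weight_kg}")
    if height_cm <= 0:
        raise DomainError(f"height_cm must be positive, got {height_cm}")
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index (kg/m²): weight over squared height in metres."""
    if weight_kg <= 0:
        raise DomainError(f"weight_kg must be positive, got {weight_kg}")
    if height_cm <= 0:
        raise DomainError(f"height_cm must be positive, got {height_cm}")
    height_m = height_cm / 100.0
    return weight_kg / (height_m * height_m)


@dataclass(frozen=True)
class AgeCorrectionPolicy:
    """Optional saturating transform of chronological age.

    Healthy reference cohorts contain few elderly subjects, so raw age
    itself can look "novel" to a support estimator.  The corrected age

        C = plateau · (1 − ((cap_age − min(age, cap_age)) / cap_age)²)

    compresses old ages onto a plateau (75 years by default, reached at
    age cap_age = 90) while leaving young ages nearly linear.  When
    ``enabled`` the transform applies both at training and scoring
    time.  Disabled by default.
    """

    enabled: bool = False
    cap_age: float = 90.0
    plateau: float = 75.0

    def __post_init__(self) -> None:
        if self.cap_age <= 0:
            raise DomainError(f"cap_age must be positive, got {self.cap_age}")
        if self.plateau <= 0:
            raise DomainError(f"plateau must be positive, got {self.plateau}")


def correct_age(age: float, policy: AgeCorrectionPolicy | None = None) -> float:
    """Apply the saturating age correction; see :class:`AgeCorrectionPolicy`.

    Monotone non-decreasing in age, equal to 0 at age 0 and constant at
    ``plateau`` for ages at or above ``cap_age``.  Applied regardless of
    the policy's ``enabled`` flag — the flag governs whether callers
    invoke the transform, not the arithmetic itself.
    """
    if policy is None:
        policy = AgeCorrectionPolicy()
    if age < 0:
        raise DomainError(f"age must be non-negative, got {age}")
    capped = min(age, policy.cap_age)
    frac = (policy.cap_age - capped) / policy.cap_age
    return policy.plateau * (1.0 - frac * frac)


@dataclass
class SubjectRecord:
    """One individual: demographics, anthropometrics, aortic diameters.

    ``diameters`` maps level name (member of :data:`LEVELS`) to mm; any
    level may be absent for partially measured subjects.  ``bsa`` is
    derived from weight/height when not supplied, and validated for
    consistency (within 0.01 m²) when it is.
    """

    subject_id: str
    age: float
    sex: str  # "F" or "M"
    height_cm: float
    weight_kg: float
    diameters: dict[str, float] = field(default_factory=dict)
    bsa: float | None = None
    group: str = "unknown"
    extras: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.age <= 120):
            raise DomainError(f"age out of range [0, 120]: {self.age}")
        if self.sex not in ("F", "M"):
            raise DomainError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.height_cm <= 0:
            raise DomainError(f"height_cm must be positive, got {self.height_cm}")
        if self.weight_kg <= 0:
            raise DomainError(f"weight_kg must be positive, got {self.weight_kg}")
        for level, value in self.diameters.items():
            if level not in LEVELS:
                raise DomainError(f"unknown aortic level {level!r}")
            if not (0 < value < 100):
                raise DomainError(f"diameter {level}={value} outside (0, 100) mm")
        if self.group not in VALID_GROUPS:
            raise DomainError(f"unknown group {self.group!r}")
        derived = compute_bsa(self.weight_kg, self.height_cm)
        if self.bsa is None:
            self.bsa = derived
        elif abs(self.bsa - derived) > 0.01:
            raise DomainError(
                f"bsa {self.bsa:.4f} inconsistent with weight/height "
                f"(derived {derived:.4f} m²)"
            )

    @property
    def is_female(self) -> bool:
        return self.sex == "F"

    def feature_value(
        self, name: str, age_policy: AgeCorrectionPolicy | None = None
    ) -> float:
        """Raw value of a named feature, before normalization.

        Sex is encoded female=1, male=0.  Age passes through the
        correction transform when the policy is enabled.
        """
        if name == "age":
            if age_policy is not None and age_policy.enabled:
                return correct_age(self.age, age_policy)
            return float(self.age)
        if name == "sex":
            return 1.0 if self.is_female else 0.0
        if name == "bsa":
            return float(self.bsa)  # type: ignore[arg-type]
        if name in LEVELS:
            if name not in self.diameters:
                raise IncompleteRecordError(
                    f"subject {self.subject_id!r} missing diameter at {name}"
                )
            return float(self.diameters[name])
        raise DomainError(f"unknown feature {name!r}")


@dataclass
class Cohort:
    """An ordered collection of subjects with unique identifiers."""

    records: list[SubjectRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = {i for i in ids if i in seen or seen.add(i)}  # type: ignore[func-returns-value]
            raise DomainError(f"duplicate subject_ids: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> SubjectRecord:
        return self.records[idx]

    def subset(self, indices: Iterable[int], label: str | None = None) -> "Cohort":
        return Cohort(
            [self.records[i] for i in indices],
            label if label is not None else self.label,
        )

    def filter(self, predicate, label: str | None = None) -> "Cohort":
        return Cohort(
            [r for r in self.records if predicate(r)],
            label if label is not None else self.label,
        )

    def adults_only(self, min_age: float = 15.0) -> "Cohort":
        """Subjects strictly older than ``min_age`` years (default >15)."""
        return self.filter(lambda r: r.age > min_age, label=f"{self.label}[adults]")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex,
                "height_cm": r.height_cm,
                "weight_kg": r.weight_kg,
                "group": r.group,
            }
            for level, col in _LEVEL_TO_CSV.items():
                row[col] = r.diameters.get(level, np.nan)
            row.update(r.extras)
            rows.append(row)
        df = pd.DataFrame(rows)
        ordered = [c for c in _CSV_COLUMNS if c in df.columns]
        extras = [c for c in df.columns if c not in _CSV_COLUMNS]
        return df[ordered + extras]

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "Cohort":
        required = [c for c in _CSV_COLUMNS if c not in _LEVEL_TO_CSV.values() and c != "group"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DomainError(f"cohort table missing columns: {missing}")
        extras_cols = [c for c in df.columns if c not in _CSV_COLUMNS]
        records = []
        for i, row in df.iterrows():
            diameters = {}
            for col, level in _CSV_TO_LEVEL.items():
                if col in df.columns and pd.notna(row[col]):
                    diameters[level] = float(row[col])
            try:
                rec = SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]).strip().upper(),
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                    diameters=diameters,
                    group=str(row["group"]) if "group" in df.columns and pd.notna(row.get("group")) else "unknown",
                    extras={c: row[c] for c in extras_cols if pd.notna(row[c])},
                )
            except (DomainError, ValueError, TypeError) as exc:
                raise DomainError(f"row {i} (subject {row.get('subject_id')!r}): {exc}") from exc
            records.append(rec)
        return cls(records, label=label)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "Cohort":
        df = pd.read_csv(path)
        return cls.from_dataframe(df, label=label if label is not None else str(path))


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-feature affine min–max map fitted on a training cohort.

    Maps each feature x to (x − min)/(max − min); training values land
    in [0, 1] by construction.  Values outside the training range are
    deliberately *not* clipped: a subject beyond the training envelope
    should look extreme to downstream models, and clipping would hide
    that.
    """

    feature_names: tuple[str, ...]
    minima: tuple[float, ...]
    maxima: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.minima) or len(self.minima) != len(self.maxima):
            raise DomainError("feature_names, minima, maxima must have equal length")
        for name, lo, hi in zip(self.feature_names, self.minima, self.maxima):
            if not hi > lo:
                raise DegenerateScaleError(
                    f"feature {name!r} has degenerate range [{lo}, {hi}]"
                )

    @property
    def spans(self) -> np.ndarray:
        return np.asarray(self.maxima) - np.asarray(self.minima)

    def transform(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        return (raw - np.asarray(self.minima)) / self.spans

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        return scaled * self.spans + np.asarray(self.minima)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "minima": list(self.minima),
            "maxima": list(self.maxima),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "NormalizationSpec":
        return cls(
            feature_names=tuple(payload["feature_names"]),
            minima=tuple(float(v) for v in payload["minima"]),
            maxima=tuple(float(v) for v in payload["maxima"]),
        )


def cohort_feature_matrix(
    cohort: Cohort,
    features: Sequence[str],
    age_policy: AgeCorrectionPolicy | None = None,
) -> np.ndarray:
    """Raw (unnormalized) feature matrix, one row per record."""
    return np.array(
        [[r.feature_value(f, age_policy) for f in features] for r in cohort],
        dtype=float,
    )


def fit_normalization(
    cohort: Cohort,
    features: Sequence[str],
    age_policy: AgeCorrectionPolicy | None = None,
) -> NormalizationSpec:
    """Fit per-feature min/max on a cohort.

    Sex is encoded (female=1, male=0) before scaling; with both sexes
    present its scaled values are exactly {0, 1}.  A feature constant on
    the cohort raises :class:`DegenerateScaleError`.
    """
    if len(cohort) == 0:
        raise DomainError("cannot fit normalization on an empty cohort")
    X = cohort_feature_matrix(cohort, features, age_policy)
    minima = X.min(axis=0)
    maxima = X.max(axis=0)
    return NormalizationSpec(
        feature_names=tuple(features),
        minima=tuple(float(v) for v in minima),
        maxima=tuple(float(v) for v in maxima),
    )


def apply_normalization(
    spec: NormalizationSpec,
    record: SubjectRecord,
    age_policy: AgeCorrectionPolicy | None = None,
) -> np.ndarray:
    """Normalized feature vector for one record, in the spec's order.

    Out-of-range values pass through the affine map unclipped.
    """
    raw = np.array(
        [record.feature_value(f, age_policy) for f in spec.feature_names],
        dtype=float,
    )
    return spec.transform(raw)
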