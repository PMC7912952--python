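"""Per-level linear regression Z-scores.

One ordinary-least-squares model per aortic level predicts the
diameter (mm) from normalized age, normalized BSA and sex, fitted on
all healthy subjects jointly (a single all-ages, both-sexes model per
level).  The residual variance is assumed homoscedastic and estimated
by the mean squared training residual, so

    z = (observed − predicted) / σ,   σ = √(MSE on training data),

and a level is called abnormal when z > 2 (one-sided; under Gaussian
residuals this is roughly the 2.3rd upper percentile).  The global
statistic for a subject is the maximum z over the measured levels,
operationalizing "abnormal at any level".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import LEVELS, Cohort, SubjectRecord
from .errors import (
    DegenerateModelError,
    DomainError,
    FitError,
    IncompleteRecordError,
)

Z_ABNORMAL_CUTOFF = 2.0

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class LinearDiameterModel:
    """OLS diameter model for one aortic level.

    Predictors are age/age_max, bsa/bsa_max and a female indicator;
    age_max and bsa_max are the training-cohort maxima, stored so that
    new subjects are normalized exactly as the training data were.
    Coefficients and sigma are on the response scale (mm).
    """

    level: str
    intercept: float
    coef_age: float
    coef_bsa: float
    coef_female: float
    age_max: float
    bsa_max: float
    sigma: float
    n_train: int

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise DomainError(f"unknown aortic level {self.level!r}")
        if self.age_max <= 0 or self.bsa_max <= 0:
            raise DomainError("age_max and bsa_max must be positive")
        if self.sigma < 0:
            raise DomainError("sigma must be non-negative")

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "kind": "linear_diameter_model",
            "level": self.level,
            "intercept": self.intercept,
            "coef_age": self.coef_age,
            "coef_bsa": self.coef_bsa,
            "coef_female": self.coef_female,
            "age_max": self.age_max,
            "bsa_max": self.bsa_max,
            "sigma": self.sigma,
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "LinearDiameterModel":
        return cls(
            level=payload["level"],
            intercept=float(payload["intercept"]),
            coef_age=float(payload["coef_age"]),
            coef_bsa=float(payload["coef_bsa"]),
            coef_female=float(payload["coef_female"]),
            age_max=float(payload["age_max"]),
            bsa_max=float(payload["bsa_max"]),
            sigma=float(payload["sigma"]),
            n_train=int(payload["n_train"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LinearDiameterModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ZScoreReport:
    """Per-level z values and categories for one subject.

    ``global_statistic`` is the maximum z over the levels present;
    ``global_abnormal`` is true iff any level exceeds the cutoff.
    """

    z: dict[str, float]
    category: dict[str, str]
    global_statistic: float
    global_abnormal: bool


def fit_linear_model(
    cohort: Cohort,
    level: str,
    min_records: int = 10,
) -> LinearDiameterModel:
    """Fit the per-level OLS diameter model on a (healthy) cohort.

    Records missing the level's diameter are dropped.  The design is
    [1, age/age_max, bsa/bsa_max, female]; a rank-deficient design
    (e.g. a single-sex cohort) raises :class:`FitError`.
    """
    if level not in LEVELS:
        raise DomainError(f"unknown aortic level {level!r}")
    usable = [r for r in cohort if level in r.diameters]
    if len(usable) < min_records:
        raise FitError(
            f"need >= {min_records} records with {level} measured, got {len(usable)}"
        )
    age = np.array([r.age for r in usable], dtype=float)
    bsa = np.array([r.bsa for r in usable], dtype=float)
    female = np.array([1.0 if r.is_female else 0.0 for r in usable])
    y = np.array([r.diameters[level] for r in usable], dtype=float)

    age_max = float(age.max())
    bsa_max = float(bsa.max())
    if age_max <= 0 or bsa_max <= 0:
        raise FitError("training cohort has non-positive age or BSA maximum")

    X = np.column_stack([np.ones_like(y), age / age_max, bsa / bsa_max, female])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"rank-deficient design for {level} (rank {rank} < {X.shape[1]}); "
            "check that both sexes and varying age/BSA are present"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ beta
    sigma = float(np.sqrt(np.mean(residuals**2)))
    return LinearDiameterModel(
        level=level,
        intercept=float(beta[0]),
        coef_age=float(beta[1]),
        coef_bsa=float(beta[2]),
        coef_female=float(beta[3]),
        age_max=age_max,
        bsa_max=bsa_max,
        sigma=sigma,
        n_train=len(usable),
    )


def predict_diameter(model: LinearDiameterModel, record: SubjectRecord) -> float:
    """Expected diameter (mm) for a subject under the fitted model."""
    return (
        model.intercept
        + model.coef_age * (record.age / model.age_max)
        + model.coef_bsa * (record.bsa / model.bsa_max)  # type: ignore[operator]
        + model.coef_female * (1.0 if record.is_female else 0.0)
    )


def z_score(
    model: LinearDiameterModel,
    record: SubjectRecord,
    observed: float | None = None,
) -> float:
    """Z-score of an observed diameter: (observed − predicted)/σ.

    ``observed`` defaults to the record's own diameter at the model's
    level.
    """
    if observed is None:
        if model.level not in record.diameters:
            raise IncompleteRecordError(
                f"subject {record.subject_id!r} missing diameter at {model.level}"
            )
        observed = record.diameters[model.level]
    if observed <= 0:
        raise DomainError(f"observed diameter must be positive, got {observed}")
    if model.sigma == 0:
        raise DegenerateModelError(
            f"model for {model.level} has sigma = 0; z-score undefined"
        )
    return (observed - predict_diameter(model, record)) / model.sigma


def z_report(
    models: Mapping[str, LinearDiameterModel],
    record: SubjectRecord,
    cutoff: float = Z_ABNORMAL_CUTOFF,
) -> ZScoreReport:
    """Score a subject at every measured level and summarize globally."""
    available = [lv for lv in LEVELS if lv in record.diameters and lv in models]
    if not available:
        raise IncompleteRecordError(
            f"subject {record.subject_id!r} has no measured level with a model"
        )
    z: dict[str, float] = {}
    category: dict[str, str] = {}
    for lv in available:
        z[lv] = z_score(models[lv], record)
        category[lv] = "abnormal" if z[lv] > cutoff else "normal"
    global_statistic = max(z.values())
    return ZScoreReport(
        z=z,
        category=category,
        global_statistic=global_statistic,
        global_abnormal=global_statistic > cutoff,
    )


def fit_all_levels(
    cohort: Cohort,
    adults_only: bool = False,
    levels: Sequence[str] = LEVELS,
) -> dict[str, LinearDiameterModel]:
    """Fit one model per level; optionally restrict to age > 15 years."""
    train = cohort.adults_only() if adults_only else cohort
    return {lv: fit_linear_model(train, lv) for lv in levels}
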