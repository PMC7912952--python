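"""ROC comparison machinery for the two calculators.

Scores are always oriented so that larger = more abnormal: the Z arm
uses the per-level z (or the max over levels for the global arm); the
Q arm uses the negated Q-score, with above-grid values mapped one grid
step above the ceiling (31%) so that all ranks are finite.

AUC equals the Mann–Whitney probability that a random patient
outranks a random healthy subject, ties counting one half.  Confidence
intervals come from stratified bootstrap percentiles, and paired AUCs
are compared with the DeLong test based on placement values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .core import LEVELS, AgeCorrectionPolicy, Cohort, SubjectRecord
from .errors import DomainError, FitError, PairingError
from .qscore import NuGrid, fit_qscore_ensemble, q_score
from .zscore import fit_all_levels, z_report, z_score

HEALTHY, PATIENT = 0, 1


@dataclass(frozen=True)
class ScoredSubject:
    """One subject's pooled out-of-fold score; larger = more abnormal."""

    subject_id: str
    label: int
    score: float

    def __post_init__(self) -> None:
        if self.label not in (HEALTHY, PATIENT):
            raise DomainError(f"label must be 0 or 1, got {self.label}")
        if not math.isfinite(self.score):
            raise DomainError(f"score must be finite, got {self.score}")


@dataclass(frozen=True)
class RocResult:
    """ROC curve with AUC, optional bootstrap CI and best operating point."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    best_cutoff: float
    sensitivity: float
    specificity: float
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def curve(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass(frozen=True)
class DeLongResult:
    """Paired comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    difference: float
    variance: float
    p_value: float


def _split_scores(scored: Sequence[ScoredSubject]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.label for s in scored])
    x = np.array([s.score for s in scored], dtype=float)
    pos = x[y == PATIENT]
    neg = x[y == HEALTHY]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("both labels must be present to compute an ROC")
    return pos, neg


def roc_auc(scored: Sequence[ScoredSubject]) -> RocResult:
    """ROC curve and AUC by threshold sweep; Mann–Whitney tie handling.

    The best cutoff maximizes sensitivity + specificity over observed
    thresholds, ties broken toward higher specificity.
    """
    _split_scores(scored)  # validates both classes present
    y = np.array([s.label for s in scored])
    x = np.array([s.score for s in scored], dtype=float)
    auc = float(roc_auc_score(y, x))
    fpr, tpr, thresholds = roc_curve(y, x)
    cutoff, sens, spec = _best_operating_point(fpr, tpr, thresholds)
    return RocResult(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        best_cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
    )


def _best_operating_point(
    fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray
) -> tuple[float, float, float]:
    youden = tpr + (1.0 - fpr)
    best = np.max(youden)
    # ties toward higher specificity = lower fpr
    candidates = np.flatnonzero(youden >= best - 1e-12)
    idx = candidates[np.argmin(fpr[candidates])]
    cutoff = float(thresholds[idx])
    if math.isinf(cutoff):  # sklearn's sentinel above the max score
        cutoff = float(np.max(thresholds[np.isfinite(thresholds)]))
    return cutoff, float(tpr[idx]), float(1.0 - fpr[idx])


def best_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing sens + spec."""
    return roc.best_cutoff, roc.sensitivity, roc.specificity


def bootstrap_auc_ci(
    scored: Sequence[ScoredSubject],
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC.

    Each replicate resamples healthy and patient subjects separately
    with replacement, so no replicate loses a class.
    """
    if B < 200:
        raise DomainError(f"B must be >= 200, got {B}")
    pos, neg = _split_scores(scored)
    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    for b in range(B):
        ps = pos[rng.integers(0, len(pos), len(pos))]
        ns = neg[rng.integers(0, len(neg), len(neg))]
        aucs[b] = roc_auc_score(labels, np.concatenate([ps, ns]))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per patient) and V01 (per healthy)."""
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 otherwise
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_test(
    scored_a: Sequence[ScoredSubject],
    scored_b: Sequence[ScoredSubject],
) -> DeLongResult:
    """DeLong test for the difference of two paired AUCs.

    Both score sets must cover the same subjects with the same labels
    (same order).  Identical score vectors give difference 0, p = 1.
    """
    if len(scored_a) != len(scored_b):
        raise PairingError("score sets have different lengths")
    for sa, sb in zip(scored_a, scored_b):
        if sa.subject_id != sb.subject_id or sa.label != sb.label:
            raise PairingError(
                f"unpaired subjects: {sa.subject_id!r}/{sa.label} vs "
                f"{sb.subject_id!r}/{sb.label}"
            )
    y = np.array([s.label for s in scored_a])
    xa = np.array([s.score for s in scored_a], dtype=float)
    xb = np.array([s.score for s in scored_b], dtype=float)
    pos_mask = y == PATIENT
    m = int(pos_mask.sum())
    n = int((~pos_mask).sum())
    if m == 0 or n == 0:
        raise DomainError("both labels must be present")

    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, x in enumerate((xa, xb)):
        p10, p01 = _placements(x[pos_mask], x[~pos_mask])
        v10[k], v01[k] = p10, p01
        aucs[k] = p10.mean()

    s10 = np.cov(v10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, ddof=1) if n > 1 else np.zeros((2, 2))
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ (s10 / m + s01 / n) @ contrast)
    diff = float(aucs[0] - aucs[1])
    if var <= 0:
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongResult(
        auc_a=float(aucs[0]),
        auc_b=float(aucs[1]),
        difference=diff,
        variance=var,
        p_value=p,
    )


ScorerMap = Mapping[str, Callable[[SubjectRecord], float]]
ScorerFactory = Callable[[Cohort], ScorerMap]


def cv_scores(
    healthy: Cohort,
    patients: Cohort,
    scorer_factory: ScorerFactory,
    k: int = 10,
    seed: int | None = None,
) -> dict[str, list[ScoredSubject]]:
    """Pooled out-of-fold scores under stratified k-fold cross-validation.

    Both classes are partitioned into k folds preserving the class
    ratio.  For each fold, ``scorer_factory`` receives the *healthy*
    subjects of the other k−1 folds only — patients never enter
    training — and returns named scoring callables; the held-out fold's
    healthy and patient subjects are then scored.  Every subject is
    scored exactly once; arms share folds, so their outputs are paired.
    """
    if k < 2:
        raise DomainError(f"k must be >= 2, got {k}")
    if len(healthy) < k or len(patients) < k:
        raise FitError(
            f"each class needs >= {k} members (got {len(healthy)} healthy, "
            f"{len(patients)} patients)"
        )
    records = list(healthy) + list(patients)
    labels = np.array([HEALTHY] * len(healthy) + [PATIENT] * len(patients))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled: dict[str, list[ScoredSubject]] = {}
    for train_idx, test_idx in skf.split(np.zeros(len(records)), labels):
        train_healthy = Cohort(
            [records[i] for i in train_idx if labels[i] == HEALTHY],
            label="cv-train",
        )
        scorers = scorer_factory(train_healthy)
        for arm, fn in scorers.items():
            bucket = pooled.setdefault(arm, [])
            for i in test_idx:
                bucket.append(
                    ScoredSubject(
                        subject_id=records[i].subject_id,
                        label=int(labels[i]),
                        score=float(fn(records[i])),
                    )
                )
    return pooled


def zq_scorer_factory(
    level: str | None = None,
    age_policy: AgeCorrectionPolicy | None = None,
    grid: NuGrid | None = None,
    gamma: float | str = "scale",
    adults_only: bool = False,
) -> ScorerFactory:
    """Factory producing paired "Z" and "Q" scorers for :func:`cv_scores`.

    ``level=None`` gives the global arms: max per-level z, and negated
    global Q.  A named level gives the per-level z and negated local Q.
    Above-grid Q maps to one step above the grid ceiling so scores stay
    finite (all above-grid subjects tie, which is exactly what the grid
    can resolve).
    """
    if level is not None and level not in LEVELS:
        raise DomainError(f"unknown aortic level {level!r}")

    def factory(train_healthy: Cohort) -> ScorerMap:
        train = train_healthy.adults_only() if adults_only else train_healthy
        scope = "global" if level is None else f"local:{level}"
        ensemble = fit_qscore_ensemble(
            train, scope, grid=grid, age_policy=age_policy, gamma=gamma
        )
        ceiling = ensemble.grid.ceiling_percent + 1.0

        def q_arm(record: SubjectRecord) -> float:
            q = q_score(ensemble, record)
            return -min(q, ceiling)

        if level is None:
            models = fit_all_levels(train)

            def z_arm(record: SubjectRecord) -> float:
                return z_report(models, record).global_statistic

        else:
            from .zscore import fit_linear_model

            model = fit_linear_model(train, level)

            def z_arm(record: SubjectRecord) -> float:
                return z_score(model, record)

        return {"Z": z_arm, "Q": q_arm}

    return factory


def prevalence_percent(n_abnormal: int, n_total: int) -> float:
    """Prevalence as a percent, rounded to one decimal (e.g. 243/351 → 69.2)."""
    if n_total <= 0:
        raise DomainError(f"n_total must be positive, got {n_total}")
    if not (0 <= n_abnormal <= n_total):
        raise DomainError(
            f"n_abnormal must be in [0, n_total], got {n_abnormal}/{n_total}"
        )
    return round(100.0 * n_abnormal / n_total, 1)


def discordance_table(z_reports: Sequence, q_reports: Sequence) -> np.ndarray:
    """2×2 counts of global Z-abnormalcy vs. global Q-abnormalcy.

    Z-abnormal: z > 2 at any level.  Q-abnormal: global Q ≤ 4%.
    Returns counts[z_abnormal][q_abnormal] (0 = no, 1 = yes).
    """
    if len(z_reports) != len(q_reports):
        raise PairingError("z_reports and q_reports must be paired 1:1")
    table = np.zeros((2, 2), dtype=int)
    for zr, qr in zip(z_reports, q_reports):
        if qr.global_q is None:
            raise PairingError("q_report without a global Q cannot be tabulated")
        zi = int(zr.global_abnormal)
        qi = int(qr.global_q <= 4.0)
        table[zi, qi] += 1
    return table
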