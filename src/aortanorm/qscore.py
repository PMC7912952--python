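"""Q-scores from an ensemble of one-class SVMs on a percentile grid.

A one-class SVM with parameter ν estimates the support of the healthy
population: after training, at most roughly a fraction ν of training
points fall outside (decision function f_ν < 0).  Training one machine
per ν on the grid 1%, 2%, …, 30% turns the uncalibrated decision
values into an interpretable percentile: the **Q-score** of a subject
is the smallest grid ν at which the subject is flagged, i.e. the
(approximate) fraction of the healthy population living in regions at
least as atypical.  A subject inside every fitted support scores
"above grid" (> 30%).

Features are age (optionally age-corrected), sex (female=1), BSA and
either one diameter (local score, per level) or all four (global
score, sensitive to overall aortic shape).  All features are min–max
normalized to the training cohort's [0, 1] range before training and
scoring; out-of-range values are not clipped.

Interpretation thresholds: Q < 2% abnormal, 2% ≤ Q ≤ 4% borderline
(both ends inclusive), Q > 4% normal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import OneClassSVM

from .core import (
    DEMOGRAPHIC_FEATURES,
    LEVELS,
    AgeCorrectionPolicy,
    Cohort,
    NormalizationSpec,
    SubjectRecord,
    apply_normalization,
    cohort_feature_matrix,
    fit_normalization,
)
from .errors import (
    ConfigurationError,
    DomainError,
    FitError,
    IncompleteRecordError,
)

Q_ABNORMAL_MAX = 2.0  # percent; q strictly below → abnormal
Q_BORDERLINE_MAX = 4.0  # percent; q in [2, 4] → borderline

#: Sentinel for "inside every fitted support": above the grid ceiling.
ABOVE_GRID = math.inf

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NuGrid:
    """Strictly increasing percentile grid for the OC-SVM ensemble."""

    values: tuple[float, ...] = tuple(round(0.01 * k, 2) for k in range(1, 31))

    def __post_init__(self) -> None:
        if not self.values:
            raise DomainError("empty nu grid")
        arr = np.asarray(self.values)
        if np.any(arr <= 0) or np.any(arr >= 1):
            raise DomainError("nu values must lie in (0, 1)")
        if np.any(np.diff(arr) <= 0):
            raise DomainError("nu grid must be strictly increasing")

    @property
    def percents(self) -> tuple[float, ...]:
        return tuple(100.0 * v for v in self.values)

    @property
    def ceiling_percent(self) -> float:
        return 100.0 * self.values[-1]


@dataclass(frozen=True)
class KernelMachine:
    """A fitted RBF one-class decision function.

    f(x) = Σ_i α_i · exp(−γ‖s_i − x‖²) − ρ, stored explicitly so that
    serialized ensembles can be evaluated without the original solver
    object.
    """

    nu: float
    gamma: float
    support_vectors: np.ndarray  # (n_sv, d)
    dual_coef: np.ndarray  # (n_sv,)
    rho: float  # offset; f(x) = K @ dual_coef − rho

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = rbf_kernel(X, self.support_vectors, gamma=self.gamma)
        return K @ self.dual_coef - self.rho

    def to_dict(self) -> dict:
        return {
            "nu": self.nu,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "KernelMachine":
        return cls(
            nu=float(payload["nu"]),
            gamma=float(payload["gamma"]),
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            rho=float(payload["rho"]),
        )


def scope_features(scope: str) -> tuple[str, ...]:
    """Feature order for a scope: 'global' or 'local:<level>'."""
    if scope == "global":
        return DEMOGRAPHIC_FEATURES + LEVELS
    if scope.startswith("local:"):
        level = scope.split(":", 1)[1]
        if level not in LEVELS:
            raise ConfigurationError(f"unknown aortic level in scope {scope!r}")
        return DEMOGRAPHIC_FEATURES + (level,)
    raise ConfigurationError(f"scope must be 'global' or 'local:<level>', got {scope!r}")


@dataclass(frozen=True)
class QScoreEnsemble:
    """One-class SVM ensemble defining local or global Q-scores."""

    scope: str
    feature_names: tuple[str, ...]
    normalization: NormalizationSpec
    grid: NuGrid
    age_policy: AgeCorrectionPolicy
    machines: tuple[KernelMachine, ...]
    n_train: int = 0

    def __post_init__(self) -> None:
        if len(self.machines) != len(self.grid.values):
            raise ConfigurationError("one kernel machine required per grid value")
        for nu, m in zip(self.grid.values, self.machines):
            if abs(m.nu - nu) > 1e-12:
                raise ConfigurationError("machine order must match the nu grid")

    def decision_matrix(self, X_scaled: np.ndarray) -> np.ndarray:
        """Decision values, shape (n_machines, n_points)."""
        X_scaled = np.atleast_2d(X_scaled)
        return np.vstack([m.decision(X_scaled) for m in self.machines])

    def q_values(self, X_scaled: np.ndarray) -> np.ndarray:
        """Q-scores in percent for pre-normalized points (inf = above grid)."""
        D = self.decision_matrix(X_scaled)  # (n_nu, n_pts)
        flagged = D < 0
        percents = np.asarray(self.grid.percents)
        out = np.full(D.shape[1], ABOVE_GRID)
        any_flag = flagged.any(axis=0)
        first = flagged.argmax(axis=0)
        out[any_flag] = percents[first[any_flag]]
        return out

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "kind": "qscore_ensemble",
            "scope": self.scope,
            "feature_names": list(self.feature_names),
            "normalization": self.normalization.to_dict(),
            "grid": list(self.grid.values),
            "age_policy": {
                "enabled": self.age_policy.enabled,
                "cap_age": self.age_policy.cap_age,
                "plateau": self.age_policy.plateau,
            },
            "machines": [m.to_dict() for m in self.machines],
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "QScoreEnsemble":
        ap = payload["age_policy"]
        return cls(
            scope=payload["scope"],
            feature_names=tuple(payload["feature_names"]),
            normalization=NormalizationSpec.from_dict(payload["normalization"]),
            grid=NuGrid(tuple(float(v) for v in payload["grid"])),
            age_policy=AgeCorrectionPolicy(
                enabled=bool(ap["enabled"]),
                cap_age=float(ap["cap_age"]),
                plateau=float(ap["plateau"]),
            ),
            machines=tuple(KernelMachine.from_dict(m) for m in payload["machines"]),
            n_train=int(payload.get("n_train", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "QScoreEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class QScoreReport:
    """Local and global Q-scores with interpretation categories.

    Values are percent on the grid; :data:`ABOVE_GRID` (inf) means the
    subject was inside every fitted support (reported as ">30%").
    ``global_q`` is None when not all four diameters are available.
    """

    local_q: dict[str, float]
    local_category: dict[str, str]
    global_q: float | None
    global_category: str | None


def q_category(q_percent: float) -> str:
    """Interpretation band: abnormal < 2%, borderline in [2%, 4%], else normal."""
    if q_percent < Q_ABNORMAL_MAX:
        return "abnormal"
    if q_percent <= Q_BORDERLINE_MAX:
        return "borderline"
    return "normal"


def format_q(q_percent: float, ceiling: float = 30.0) -> str:
    """Render a Q-score: '7%' or '>30%' for above-grid values."""
    if math.isinf(q_percent) or q_percent > ceiling:
        return f">{ceiling:g}%"
    return f"{q_percent:g}%"


def _resolve_gamma(gamma: float | str, X: np.ndarray) -> float:
    """RBF bandwidth: 'median' heuristic, 'scale' rule, or a number."""
    if gamma == "median":
        from scipy.spatial.distance import pdist

        med = float(np.median(pdist(X)))
        if med <= 0:
            raise FitError("degenerate training matrix: median pairwise distance 0")
        return 1.0 / (2.0 * med * med)
    if gamma == "scale":
        var = float(X.var())
        if var <= 0:
            raise FitError("zero variance in normalized training features")
        return 1.0 / (X.shape[1] * var)
    value = float(gamma)
    if value <= 0:
        raise DomainError(f"gamma must be positive, got {value}")
    return value


def fit_qscore_ensemble(
    cohort: Cohort,
    scope: str,
    grid: NuGrid | None = None,
    age_policy: AgeCorrectionPolicy | None = None,
    gamma: float | str = "scale",
    min_records: int = 50,
    tol: float = 1e-6,
) -> QScoreEnsemble:
    """Train one one-class SVM per grid ν on the scope's features.

    Records missing a required diameter are dropped; at least
    ``min_records`` complete records are required.  Age correction, when
    enabled in ``age_policy``, is applied before normalization is
    fitted.  ``gamma='scale'`` (default) is the variance rule
    1/(d·var(X)) on the normalized training matrix; ``gamma='median'``
    (the median-pairwise-distance heuristic 1/(2·m²)) is smoother and
    is also accepted.  Fitting is deterministic given
    cohort, grid and kernel parameters.
    """
    if grid is None:
        grid = NuGrid()
    if age_policy is None:
        age_policy = AgeCorrectionPolicy()
    features = scope_features(scope)

    def complete(r: SubjectRecord) -> bool:
        return all(f in r.diameters for f in features if f in LEVELS)

    usable = cohort.filter(complete)
    if len(usable) < min_records:
        raise FitError(
            f"scope {scope!r} needs >= {min_records} complete records, "
            f"got {len(usable)}"
        )
    normalization = fit_normalization(usable, features, age_policy)
    raw = cohort_feature_matrix(usable, features, age_policy)
    X = normalization.transform(raw)

    gamma_value = _resolve_gamma(gamma, X)

    machines = []
    for nu in grid.values:
        svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma_value, tol=tol)
        svm.fit(X)
        machines.append(
            KernelMachine(
                nu=nu,
                gamma=gamma_value,
                support_vectors=np.asarray(svm.support_vectors_, dtype=float),
                dual_coef=np.asarray(svm.dual_coef_, dtype=float).ravel(),
                rho=float(svm.intercept_[0]) * -1.0,
            )
        )
    return QScoreEnsemble(
        scope=scope,
        feature_names=features,
        normalization=normalization,
        grid=grid,
        age_policy=age_policy,
        machines=tuple(machines),
        n_train=len(usable),
    )


def q_score(ensemble: QScoreEnsemble, record: SubjectRecord) -> float:
    """Q-score (percent) of one subject: smallest flagged grid ν.

    Returns :data:`ABOVE_GRID` (inf) when the subject lies inside every
    fitted support; use :func:`format_q` to render it as ">30%".
    """
    x = apply_normalization(ensemble.normalization, record, ensemble.age_policy)
    return float(ensemble.q_values(x[None, :])[0])


def q_report(
    local_ensembles: Mapping[str, QScoreEnsemble],
    global_ensemble: QScoreEnsemble | None,
    record: SubjectRecord,
) -> QScoreReport:
    """Four local Q-scores plus the global one, with categories.

    Local scores are computed for every level whose diameter is present
    and has an ensemble; the global score requires all four diameters
    (None otherwise).  All ensembles must share one age policy.
    """
    policies = [e.age_policy for e in local_ensembles.values()]
    if global_ensemble is not None:
        policies.append(global_ensemble.age_policy)
    if len({(p.enabled, p.cap_age, p.plateau) for p in policies}) > 1:
        raise ConfigurationError("ensembles trained with differing age policies")
    for level, ens in local_ensembles.items():
        if ens.scope != f"local:{level}":
            raise ConfigurationError(
                f"ensemble under key {level!r} has scope {ens.scope!r}"
            )
    if global_ensemble is not None and global_ensemble.scope != "global":
        raise ConfigurationError(
            f"global ensemble has scope {global_ensemble.scope!r}"
        )

    local_q: dict[str, float] = {}
    local_category: dict[str, str] = {}
    for level in LEVELS:
        if level in local_ensembles and level in record.diameters:
            q = q_score(local_ensembles[level], record)
            local_q[level] = q
            local_category[level] = q_category(q)
    if not local_q and global_ensemble is None:
        raise IncompleteRecordError(
            f"subject {record.subject_id!r}: no scoreable level"
        )

    global_q: float | None = None
    global_category: str | None = None
    if global_ensemble is not None and all(lv in record.diameters for lv in LEVELS):
        global_q = q_score(global_ensemble, record)
        global_category = q_category(global_q)
    return QScoreReport(
        local_q=local_q,
        local_category=local_category,
        global_q=global_q,
        global_category=global_category,
    )


@dataclass(frozen=True)
class HeatmapResult:
    """Q-score lattice over two diameter features plus level-set contours."""

    feature_x: str
    feature_y: str
    x: np.ndarray  # lattice x coordinates (mm)
    y: np.ndarray  # lattice y coordinates (mm)
    q: np.ndarray  # (len(y), len(x)) percent values; inf = above grid
    contours: dict[float, list[np.ndarray]]  # level -> list of (k, 2) polylines
    guideline_mm: float = 40.0

    def guideline_mask(self) -> np.ndarray:
        """Lattice cells inside the dilatation region (either axis > 40 mm)."""
        XX, YY = np.meshgrid(self.x, self.y)
        return (XX > self.guideline_mm) | (YY > self.guideline_mm)

    def to_dataframe(self):
        import pandas as pd

        XX, YY = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                self.feature_x: XX.ravel(),
                self.feature_y: YY.ravel(),
                "q_percent": self.q.ravel(),
            }
        )


def q_heatmap(
    cohort: Cohort,
    feature_pair: tuple[str, str] = ("PAA", "SoV"),
    resolution: int = 60,
    margin: float = 0.25,
    grid: NuGrid | None = None,
    gamma: float | str = "scale",
    contour_levels: tuple[float, ...] = (Q_ABNORMAL_MAX, Q_BORDERLINE_MAX),
) -> HeatmapResult:
    """Two-diameter Q-score map with 2%/4% level-set contours.

    Fits a diameters-only ensemble (no demographics) on the pair,
    evaluates Q on a rectangular lattice extended ``margin`` (fraction
    of the data range) beyond the training envelope, and extracts the
    requested level sets.  Above-grid lattice cells are treated as one
    grid step above the ceiling (31%) when contouring.
    """
    fx, fy = feature_pair
    for f in (fx, fy):
        if f not in LEVELS:
            raise ConfigurationError(f"heatmap features must be aortic levels, got {f!r}")
    if resolution < 2:
        raise DomainError(f"resolution must be >= 2, got {resolution}")
    if grid is None:
        grid = NuGrid()

    usable = cohort.filter(lambda r: fx in r.diameters and fy in r.diameters)
    if len(usable) < 50:
        raise FitError(f"need >= 50 records with both {fx} and {fy}, got {len(usable)}")
    features = (fx, fy)
    normalization = fit_normalization(usable, features)
    raw = cohort_feature_matrix(usable, features)
    X = normalization.transform(raw)
    gamma_value = _resolve_gamma(gamma, X)
    machines = []
    for nu in grid.values:
        svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma_value).fit(X)
        machines.append(
            KernelMachine(
                nu=nu,
                gamma=gamma_value,
                support_vectors=np.asarray(svm.support_vectors_, dtype=float),
                dual_coef=np.asarray(svm.dual_coef_, dtype=float).ravel(),
                rho=float(svm.intercept_[0]) * -1.0,
            )
        )
    ensemble = QScoreEnsemble(
        scope=f"local:{fx}",  # scope label is nominal; features are the pair
        feature_names=features,
        normalization=normalization,
        grid=grid,
        age_policy=AgeCorrectionPolicy(),
        machines=tuple(machines),
        n_train=len(usable),
    )

    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    pad = margin * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], resolution)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], resolution)
    XX, YY = np.meshgrid(xs, ys)
    pts_raw = np.column_stack([XX.ravel(), YY.ravel()])
    pts = normalization.transform(pts_raw)
    q = ensemble.q_values(pts).reshape(len(ys), len(xs))

    finite_q = np.where(np.isinf(q), grid.ceiling_percent + 1.0, q)
    contours = _extract_contours(xs, ys, finite_q, contour_levels)
    return HeatmapResult(
        feature_x=fx, feature_y=fy, x=xs, y=ys, q=q, contours=contours
    )


def _extract_contours(
    xs: np.ndarray,
    ys: np.ndarray,
    values: np.ndarray,
    levels: Sequence[float],
) -> dict[float, list[np.ndarray]]:
    """Level-set polylines in data coordinates via matplotlib's contour engine."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    try:
        out: dict[float, list[np.ndarray]] = {}
        for level in levels:
            cs = ax.contour(xs, ys, values, levels=[level])
            segs: list[np.ndarray] = []
            for seg_list in cs.allsegs:
                segs.extend(np.asarray(s) for s in seg_list if len(s) > 1)
            out[float(level)] = segs
    finally:
        plt.close(fig)
    return out


def fit_all_ensembles(
    cohort: Cohort,
    grid: NuGrid | None = None,
    age_policy: AgeCorrectionPolicy | None = None,
    gamma: float | str = "scale",
    adults_only: bool = False,
) -> tuple[dict[str, QScoreEnsemble], QScoreEnsemble]:
    """Four local ensembles (one per level) plus the global one."""
    train = cohort.adults_only() if adults_only else cohort
    locals_ = {
        lv: fit_qscore_ensemble(train, f"local:{lv}", grid, age_policy, gamma)
        for lv in LEVELS
    }
    global_ = fit_qscore_ensemble(train, "global", grid, age_policy, gamma)
    return locals_, global_
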