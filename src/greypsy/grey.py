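"""Fixed-weight grey clustering over psychological evaluation indices.

The evaluation assigns each patient to one of three ordered grey classes
(good < ordinary < morbid) from per-index observations :math:`x_{ij}`:

1.  Each index's boundary points :math:`a_1 < a_2 < a_3 < a_4` yield three
    class centers :math:`\\lambda_k = (a_k + a_{k+1})/2`.
2.  A triangular (center-point) whitening weight function
    :math:`f_j^k(x)` peaks at 1 on the class center and falls linearly to
    0 on the adjacent centers.  The extreme classes are shoulder
    functions: class 1 stays at 1 below its own center, class 3 stays at
    1 above its own center.  The three functions form a partition of
    unity over the whole measurement range.
3.  Index weights are score proportions :math:`Z_j = E_j / \\sum_j E_j`.
4.  The comprehensive clustering coefficient
    :math:`\\sigma_i^k = \\sum_j f_j^k(x_{ij})\\, Z_j` classifies patient
    ``i`` into the class maximizing :math:`\\sigma_i^k`; ties resolve to
    the most severe tied class (clinically conservative).

The raw overall score :math:`\\sum_j x_{ij}` gives a coarse bifurcation:
above the threshold (default 100 points) a patient leans morbid, below it
ordinary.

`GreyClusterEvaluator` packages the procedure as a scikit-learn style
estimator; the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .indices import ConfigurationError, IndexDefinition, IndexSystem, default_index_system

__all__ = [
    "GreyClass",
    "ScoreClass",
    "DataError",
    "EvaluationError",
    "PatientIndicators",
    "ClusteringResult",
    "Reevaluation",
    "GreyClusterEvaluator",
    "compute_centers",
    "whitening_weight",
    "index_weights",
    "clustering_coefficients",
    "assign_class",
    "overall_score",
    "score_class",
    "evaluate_cohort",
    "reevaluate",
]


class GreyClass(enum.IntEnum):
    """Ordered severity classes; higher value = worse state."""

    GOOD = 1
    ORDINARY = 2
    MORBID = 3


class ScoreClass(enum.Enum):
    """Coarse classification by raw overall score."""

    ORDINARY_LEANING = "ordinary-leaning"
    MORBID_LEANING = "morbid-leaning"
    BOUNDARY = "boundary"


class DataError(ValueError):
    """Raised for invalid or incomplete patient data."""


class EvaluationError(ValueError):
    """Raised when a patient cannot be classified."""


@dataclass(frozen=True)
class PatientIndicators:
    """One patient's per-index observations, ordered as in the index system."""

    patient_id: str
    observations: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "observations", tuple(float(v) for v in self.observations)
        )

    @classmethod
    def from_mapping(
        cls, patient_id: str, values: Mapping[str, float], system: IndexSystem
    ) -> "PatientIndicators":
        missing = [n for n in system.names if n not in values]
        if missing:
            raise DataError(
                f"patient {patient_id!r}: missing observation(s) for "
                f"index(es) {missing}"
            )
        return cls(patient_id, tuple(float(values[n]) for n in system.names))


@dataclass(frozen=True)
class ClusteringResult:
    """Evaluation outcome for one patient."""

    patient_id: str
    coefficients: tuple[float, float, float]
    assigned_class: GreyClass
    overall_score: float
    score_class: ScoreClass

    def coefficient(self, k: GreyClass) -> float:
        return self.coefficients[int(k) - 1]


def compute_centers(index: IndexDefinition) -> tuple[float, float, float]:
    """Class centers of one index: midpoints of consecutive boundaries."""
    return index.centers


def whitening_weight(
    x: float | np.ndarray,
    centers: Sequence[float],
    k: GreyClass | int,
) -> float | np.ndarray:
    """Membership of observation ``x`` in grey class ``k``.

    Triangular for the middle class, shoulder for the extremes; exactly 1
    at the class's own center.  Total over the three classes is 1 for
    every finite ``x``.
    """
    l1, l2, l3 = (float(c) for c in centers)
    if not l1 < l2 < l3:
        raise ConfigurationError(f"centers must be strictly increasing, got {centers}")
    x = np.asarray(x, dtype=float)
    k = int(k)
    if k == 1:
        w = np.where(x <= l1, 1.0, np.where(x < l2, (l2 - x) / (l2 - l1), 0.0))
    elif k == 2:
        w = np.where(
            (x > l1) & (x <= l2),
            (x - l1) / (l2 - l1),
            np.where((x > l2) & (x < l3), (l3 - x) / (l3 - l2), 0.0),
        )
    elif k == 3:
        w = np.where(x <= l2, 0.0, np.where(x < l3, (x - l2) / (l3 - l2), 1.0))
    else:
        raise ValueError(f"grey class must be 1, 2 or 3, got {k}")
    return w if w.ndim else float(w)


def index_weights(system: IndexSystem) -> np.ndarray:
    """Score-proportion weights Z_j = E_j / Total."""
    return system.weights


class GreyClusterEvaluator(TransformerMixin, BaseEstimator):
    """Fixed-weight grey clustering evaluator.

    A rule-based classifier/transformer: class memberships come from
    triangular whitening weight functions anchored on the index system's
    boundary configuration, not from training data.  ``fit`` validates
    the configuration and precomputes the class centers and index
    weights.

    Parameters
    ----------
    system : IndexSystem, optional
        Evaluation index system.  Defaults to the packaged six-index
        system (Total = 200).
    score_threshold : float, default=100.0
        Raw overall-score value separating ordinary-leaning from
        morbid-leaning patients.

    Attributes
    ----------
    centers_ : ndarray of shape (n_indices, 3)
        Per-index grey-class centers.
    weights_ : ndarray of shape (n_indices,)
        Score-proportion index weights, summing to 1.
    n_features_in_ : int
        Number of indices.
    feature_names_in_ : ndarray of str
        Index names.
    """

    def __init__(self, system: IndexSystem | None = None, score_threshold: float = 100.0):
        self.system = system
        self.score_threshold = score_threshold

    def fit(self, X=None, y=None) -> "GreyClusterEvaluator":
        """Validate the index system and precompute centers and weights."""
        system = self.system if self.system is not None else default_index_system()
        self.system_ = system
        self.centers_ = system.center_matrix
        self.weights_ = system.weights
        self.n_features_in_ = len(system)
        self.feature_names_in_ = np.asarray(system.names, dtype=object)
        return self

    def _validate(self, X) -> np.ndarray:
        check_is_fitted(self, "centers_")
        X = check_array(X, dtype=float, ensure_2d=True)
        if X.shape[1] != self.n_features_in_:
            raise DataError(
                f"expected {self.n_features_in_} indicator columns "
                f"({list(self.feature_names_in_)}), got {X.shape[1]}"
            )
        full = self.system_.full_scores
        low = X < 0
        high = X > full[np.newaxis, :]
        if low.any() or high.any():
            i, j = np.argwhere(low | high)[0]
            raise DataError(
                f"observation {X[i, j]} for index "
                f"{self.feature_names_in_[j]!r} (row {i}) outside "
                f"[0, {full[j]}]"
            )
        return X

    def memberships(self, X) -> np.ndarray:
        """Whitening weights f_j^k(x_ij), shape (n_patients, n_indices, 3)."""
        X = self._validate(X)
        F = np.empty(X.shape + (3,), dtype=float)
        for j in range(self.n_features_in_):
            for k in (1, 2, 3):
                F[:, j, k - 1] = whitening_weight(X[:, j], self.centers_[j], k)
        return F

    def predict_proba(self, X) -> np.ndarray:
        """Comprehensive clustering coefficients σ^k, shape (n_patients, 3).

        Rows sum to 1 (partition of unity of the whitening weights and
        normalized index weights)."""
        F = self.memberships(X)
        return np.einsum("ijk,j->ik", F, self.weights_)

    def transform(self, X) -> np.ndarray:
        """Alias for :meth:`predict_proba` (sklearn pipeline compatibility)."""
        return self.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        """Assigned grey class per patient (1=good, 2=ordinary, 3=morbid)."""
        sigma = self.predict_proba(X)
        return np.array([int(assign_class(row)) for row in sigma])

    def overall_scores(self, X) -> np.ndarray:
        """Unweighted raw sum of observations per patient."""
        return self._validate(X).sum(axis=1)

    def evaluate(self, patients: Sequence[PatientIndicators]) -> list[ClusteringResult]:
        """Full per-patient evaluation of a cohort; order-preserving."""
        check_is_fitted(self, "centers_")
        results: list[ClusteringResult] = []
        for p in patients:
            if len(p.observations) != self.n_features_in_:
                raise DataError(
                    f"patient {p.patient_id!r}: expected "
                    f"{self.n_features_in_} observations, got "
                    f"{len(p.observations)}"
                )
            row = np.asarray(p.observations, dtype=float)[np.newaxis, :]
            try:
                sigma = self.predict_proba(row)[0]
                score = float(row.sum())
            except DataError as exc:
                raise DataError(f"patient {p.patient_id!r}: {exc}") from exc
            results.append(
                ClusteringResult(
                    patient_id=p.patient_id,
                    coefficients=tuple(float(s) for s in sigma),
                    assigned_class=assign_class(sigma),
                    overall_score=score,
                    score_class=score_class(score, self.score_threshold),
                )
            )
        return results


def clustering_coefficients(
    patient: PatientIndicators, system: IndexSystem
) -> ClusteringResult:
    """Evaluate a single patient against an index system."""
    ev = GreyClusterEvaluator(system=system).fit()
    return ev.evaluate([patient])[0]


def assign_class(coefficients: Sequence[float]) -> GreyClass:
    """Argmax of the clustering coefficients; ties go to the most severe class."""
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (3,):
        raise EvaluationError(f"expected three coefficients, got shape {c.shape}")
    if not np.all(np.isfinite(c)) or np.any(c < 0):
        raise EvaluationError(f"coefficients must be finite and non-negative: {c}")
    if np.all(c == 0):
        raise EvaluationError("all clustering coefficients are zero; cannot classify")
    # argmax on the reversed vector prefers the most severe tied class
    return GreyClass(3 - int(np.argmax(c[::-1])))


def overall_score(patient: PatientIndicators) -> float:
    """Unweighted sum of a patient's observations."""
    if not patient.observations:
        raise DataError(f"patient {patient.patient_id!r}: no observations")
    return float(sum(patient.observations))


def score_class(score: float, threshold: float = 100.0) -> ScoreClass:
    """Bifurcate a raw overall score at the threshold.

    Scores exactly on the threshold are 'boundary' and left to the
    clustering coefficients to resolve.
    """
    if score < 0:
        raise DataError(f"overall score must be non-negative, got {score}")
    if score > threshold:
        return ScoreClass.MORBID_LEANING
    if score < threshold:
        return ScoreClass.ORDINARY_LEANING
    return ScoreClass.BOUNDARY


def evaluate_cohort(
    patients: Sequence[PatientIndicators], system: IndexSystem
) -> list[ClusteringResult]:
    """Evaluate every patient; deterministic and order-preserving."""
    return GreyClusterEvaluator(system=system).fit().evaluate(patients)


@dataclass(frozen=True)
class Reevaluation:
    """Before/after comparison of two evaluations of the same cohort."""

    patient_ids: tuple[str, ...]
    deltas: np.ndarray  # (n, 3) σ_after − σ_before
    transitions: tuple[tuple[GreyClass, GreyClass], ...]
    mean_delta_good_by_baseline: dict[GreyClass, float]

    def n_improved(self) -> int:
        """Patients whose good-class coefficient increased."""
        return int(np.sum(self.deltas[:, 0] > 0))


def reevaluate(
    before: Sequence[ClusteringResult], after: Sequence[ClusteringResult]
) -> Reevaluation:
    """Per-patient coefficient deltas and class transitions after intervention.

    The cohort summary reports the mean change in the good-class
    coefficient grouped by baseline class, the quantity on which a
    successful intervention shows the largest gain for baseline-morbid
    patients.
    """
    before_by_id = {r.patient_id: r for r in before}
    after_by_id = {r.patient_id: r for r in after}
    missing_after = sorted(set(before_by_id) - set(after_by_id))
    missing_before = sorted(set(after_by_id) - set(before_by_id))
    if missing_after or missing_before:
        raise DataError(
            "unmatched patient identifiers between evaluations: "
            f"only-before={missing_after}, only-after={missing_before}"
        )
    ids = tuple(r.patient_id for r in before)
    deltas = np.array(
        [
            np.subtract(after_by_id[i].coefficients, before_by_id[i].coefficients)
            for i in ids
        ],
        dtype=float,
    ).reshape(len(ids), 3)
    transitions = tuple(
        (before_by_id[i].assigned_class, after_by_id[i].assigned_class) for i in ids
    )
    mean_by_baseline: dict[GreyClass, float] = {}
    baseline = np.array([int(before_by_id[i].assigned_class) for i in ids])
    for k in GreyClass:
        mask = baseline == int(k)
        if mask.any():
            mean_by_baseline[k] = float(deltas[mask, 0].mean())
    return Reevaluation(
        patient_ids=ids,
        deltas=deltas,
        transitions=transitions,
        mean_delta_good_by_baseline=mean_by_baseline,
    )
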