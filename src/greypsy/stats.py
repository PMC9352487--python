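"""Two-arm comparison battery: t / ANOVA for measurements, χ² / Fisher for counts.

Implements the statistical layer of the trial analysis: independent-sample
t-tests (pooled by default, Welch by flag), one-way ANOVA, Pearson χ² with
an automatic Yates continuity-correction policy (applied iff any expected
cell count is below 5), the two-sided Fisher exact test, and the derived
clinical rates and scale thresholds (IIEF-5 < 22 → erectile dysfunction;
HAMA ≥ 7 → anxiety; HAMD ≥ 7 → depression; satisfaction = (high +
normal) / total).

All p-values come from the exact reference distributions in scipy, never
from lookup tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "ContingencyTable",
    "TestResult",
    "two_sample_t",
    "two_sample_t_from_data",
    "one_way_anova_F",
    "chi2_test",
    "fisher_exact",
    "satisfaction_rate",
    "complication_summary",
    "threshold_flags",
]

COMPLICATION_CATEGORIES = (
    "urinary_incontinence",
    "urinary_infection",
    "urinary_retention",
    "urethral_bleeding",
    "other",
    "none",
)


class StatsError(ValueError):
    """Raised for statistically degenerate inputs."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of one arm-by-category comparison."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise StatsError("contingency table must be two-dimensional")
        if (counts < 0).any():
            raise StatsError("contingency table counts must be non-negative")
        if counts.shape[0] != len(self.row_labels) or counts.shape[1] != len(
            self.col_labels
        ):
            raise StatsError("label lengths must match table shape")

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[Sequence[int]],
        row_labels: Sequence[str] | None = None,
        col_labels: Sequence[str] | None = None,
    ) -> "ContingencyTable":
        counts = np.asarray(counts, dtype=int)
        rows = tuple(row_labels) if row_labels else tuple(
            f"row{i}" for i in range(counts.shape[0])
        )
        cols = tuple(col_labels) if col_labels else tuple(
            f"col{j}" for j in range(counts.shape[1])
        )
        return cls(counts, rows, cols)


@dataclass(frozen=True)
class TestResult:
    """Statistic, degrees of freedom and p-value of one comparison."""

    name: Literal["t", "F", "chi2", "fisher"]
    value: float
    df: float | tuple[float, float] | None
    p_value: float
    correction_applied: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "value": self.value,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_value": self.p_value,
            "correction_applied": self.correction_applied,
        }


def two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    *,
    welch: bool = False,
) -> TestResult:
    """Independent two-sample t-test from summary statistics.

    Pooled (Student) by default: the trial's arms are equal-sized.
    """
    if n1 < 2 or n2 < 2:
        raise StatsError(f"each group needs n >= 2, got n1={n1}, n2={n2}")
    if sd1 <= 0 or sd2 <= 0:
        raise StatsError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    df = res.df if welch else n1 + n2 - 2
    return TestResult("t", float(res.statistic), float(df), float(res.pvalue))


def two_sample_t_from_data(
    x1: Sequence[float], x2: Sequence[float], *, welch: bool = False
) -> TestResult:
    """Independent two-sample t-test from raw columns."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise StatsError("each group needs at least two observations")
    res = sps.ttest_ind(x1, x2, equal_var=not welch)
    df = res.df if welch else len(x1) + len(x2) - 2
    return TestResult("t", float(res.statistic), float(df), float(res.pvalue))


def one_way_anova_F(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F-test across two or more groups.

    For two groups F equals the square of the pooled two-sample t.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("ANOVA requires at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise StatsError("every group needs at least two observations")
    stat, p = sps.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))
    return TestResult("F", float(stat), df, float(p))


def _expected_counts(counts: np.ndarray) -> np.ndarray:
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    return row * col / counts.sum()


def chi2_test(
    table: ContingencyTable | Sequence[Sequence[int]],
    correction: Literal["auto", "on", "off"] = "auto",
) -> TestResult:
    """Pearson χ² test of independence on an arm-by-category table.

    ``correction='auto'`` applies the Yates continuity correction exactly
    when any expected cell count is below 5 (2×2 tables only; scipy
    never corrects larger tables).
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_counts(table)
    counts = table.counts
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise StatsError("contingency table has a zero marginal total")
    expected = _expected_counts(counts)
    if correction == "auto":
        apply = bool(expected.min() < 5)
    elif correction == "on":
        apply = True
    elif correction == "off":
        apply = False
    else:
        raise ValueError(f"correction must be auto|on|off, got {correction!r}")
    res = sps.chi2_contingency(counts, correction=apply)
    corrected = apply and counts.shape == (2, 2)
    return TestResult(
        "chi2", float(res.statistic), float(res.dof), float(res.pvalue), corrected
    )


def fisher_exact(
    table: ContingencyTable | Sequence[Sequence[int]],
) -> TestResult:
    """Two-sided Fisher exact test on a 2×2 table.

    The p-value sums hypergeometric probabilities (margins fixed) of all
    tables no more probable than the observed one.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable.from_counts(table)
    if table.counts.shape != (2, 2):
        raise StatsError(
            f"Fisher exact test requires a 2x2 table, got {table.counts.shape}"
        )
    res = sps.fisher_exact(table.counts, alternative="two-sided")
    return TestResult("fisher", float(res.statistic), None, float(res.pvalue))


def satisfaction_rate(high: int, normal: int, dissatisfied: int) -> float:
    """Satisfaction percentage: (high + normal) / total × 100, to 2 d.p."""
    if min(high, normal, dissatisfied) < 0:
        raise StatsError("satisfaction counts must be non-negative")
    total = high + normal + dissatisfied
    if total == 0:
        raise StatsError("satisfaction rate undefined for an empty group")
    return round((high + normal) / total * 100.0, 2)


def complication_summary(records, arm: str) -> pd.DataFrame:
    """Per-category complication counts and percentages for one arm.

    ``records`` is a cohort DataFrame (columns ``arm``, ``complication``)
    or an iterable of objects with those attributes.  The ``total`` row
    is the share of patients with any complication.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [(r.arm, r.complication) for r in records],
            columns=["arm", "complication"],
        )
    sub = df[df["arm"] == arm]
    n = len(sub)
    if n == 0:
        raise StatsError(f"no records for arm {arm!r}")
    counts = sub["complication"].value_counts()
    rows = []
    for cat in COMPLICATION_CATEGORIES:
        if cat == "none":
            continue
        c = int(counts.get(cat, 0))
        rows.append({"category": cat, "count": c, "percent": round(c / n * 100, 2)})
    any_comp = int(n - counts.get("none", 0))
    rows.append(
        {"category": "total", "count": any_comp, "percent": round(any_comp / n * 100, 2)}
    )
    return pd.DataFrame(rows)


IIEF5_ED_THRESHOLD = 22  # score below this flags erectile dysfunction
HAMA_THRESHOLD = 7  # score at or above flags anxiety
HAMD_THRESHOLD = 7  # score at or above flags depression


def threshold_flags(record) -> dict[str, dict[str, bool]]:
    """Clinical flags per timepoint from a patient's scale scores.

    Erectile dysfunction iff IIEF-5 < 22 (a score of exactly 22 is
    normal); anxiety iff HAMA ≥ 7; depression iff HAMD ≥ 7.
    """
    def get(name: str) -> float:
        v = record[name] if isinstance(record, (dict, pd.Series)) else getattr(record, name, None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise StatsError(f"missing scale value {name!r}")
        return float(v)

    return {
        "pre": {
            "erectile_dysfunction": get("iief5_pre") < IIEF5_ED_THRESHOLD,
            "anxiety": get("hama_pre") >= HAMA_THRESHOLD,
            "depression": get("hamd_pre") >= HAMD_THRESHOLD,
        },
        "post": {
            "erectile_dysfunction": get("iief5_post") < IIEF5_ED_THRESHOLD,
            "anxiety": get("hama_post") >= HAMA_THRESHOLD,
            "depression": get("hamd_post") >= HAMD_THRESHOLD,
        },
    }
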