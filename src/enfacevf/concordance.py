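"""Estimated-vs-actual visual field concordance statistics.

The estimated field is a two-gradation (defect / no defect) map derived
from NFB presence; the actual field flags each of the 68 points by its
probability-plot category in total deviation (TD) or pattern deviation
(PD).  Agreement is scored per eye by a 2x2 confusion table:

* positive        — defect in both fields
* negative        — defect in neither
* false positive  — defect only in the estimated field
* false negative  — defect only in the actual field

accuracy = (positive + negative) / 68 x 100, and Cohen's kappa is computed
from the same four cells.  Statistics are computed per eye and then
averaged over the cohort (not pooled over points); cluster-restricted
accuracies and a high-myopia split at -6 D complete the report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import FieldGrid, Laterality

N_POINTS = 68

#: Reliability limits: fixation loss, false positives, false negatives.
#: All three are strict upper bounds.
RELIABILITY_LIMITS = (0.25, 0.20, 0.33)


class ProbCategory(IntEnum):
    """Probability-plot category per point, ordered by abnormality.

    Categories nest: a point printed as <1% is a fortiori <2% and <5%.
    """

    NORMAL = 0
    P5 = 1  # < 5%
    P2 = 2  # < 2%
    P1 = 3  # < 1%
    P05 = 4  # < 0.5%

    @classmethod
    def from_label(cls, label: str) -> "ProbCategory":
        key = str(label).strip().lower().replace(" ", "")
        table = {
            "normal": cls.NORMAL,
            "<5%": cls.P5,
            "<2%": cls.P2,
            "<1%": cls.P1,
            "<0.5%": cls.P05,
        }
        if key not in table:
            raise ValueError(f"unknown probability category {label!r}")
        return table[key]

    @property
    def label(self) -> str:
        return ["normal", "<5%", "<2%", "<1%", "<0.5%"][int(self)]


#: Threshold (percent) -> minimal flagged category.
_THRESHOLD_TO_CATEGORY = {5: ProbCategory.P5, 2: ProbCategory.P2, 1: ProbCategory.P1}


@dataclass
class VisualFieldExam:
    """One eye's 10-2 exam: per-point values plus reliability metadata."""

    sensitivity_db: np.ndarray
    td_db: np.ndarray
    pd_db: np.ndarray
    td_prob: np.ndarray  # ProbCategory codes
    pd_prob: np.ndarray
    fixation_loss_rate: float
    false_pos_rate: float
    false_neg_rate: float
    md_10_2: float
    spherical_equivalent: float
    laterality: Laterality | str = Laterality.OD

    def __post_init__(self) -> None:
        self.laterality = Laterality(self.laterality)
        for name in ("sensitivity_db", "td_db", "pd_db", "td_prob", "pd_prob"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (N_POINTS,):
                raise ValueError(f"{name} must have {N_POINTS} entries")
            setattr(self, name, arr)
        for rate in (
            self.fixation_loss_rate,
            self.false_pos_rate,
            self.false_neg_rate,
        ):
            if not (0 <= rate <= 1):
                raise ValueError("reliability rates must be fractions in [0, 1]")


@dataclass(frozen=True)
class EstimatedField:
    """Binary estimated field in visual-field orientation."""

    defect: np.ndarray
    orientation: str = "field"

    def __post_init__(self) -> None:
        d = np.asarray(self.defect, dtype=bool)
        if d.shape != (N_POINTS,):
            raise ValueError(f"estimated field must have {N_POINTS} entries")
        object.__setattr__(self, "defect", d)


@dataclass(frozen=True)
class ConfusionCounts:
    positive: int
    negative: int
    false_positive: int
    false_negative: int

    @property
    def total(self) -> int:
        return (
            self.positive
            + self.negative
            + self.false_positive
            + self.false_negative
        )


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement statistics for one eye at one (metric, threshold) cell."""

    counts: ConfusionCounts
    accuracy_pct: float
    kappa: float
    cluster_accuracy: dict[str, float]
    metric: str
    threshold: int


def check_reliability(exam: VisualFieldExam) -> bool:
    """Exam QC: fixation loss < 25%, FP < 20%, FN < 33%, all strict."""
    fl, fp, fn = RELIABILITY_LIMITS
    return (
        exam.fixation_loss_rate < fl
        and exam.false_pos_rate < fp
        and exam.false_neg_rate < fn
    )


def defect_flags(
    exam: VisualFieldExam, metric: str, threshold: int
) -> np.ndarray:
    """Per-point defect flags from the probability plot.

    A point is a defect when its printed category is at or beyond the
    requested threshold; e.g. threshold 2 flags <2%, <1% and <0.5%.
    """
    metric = metric.upper()
    if metric not in ("TD", "PD"):
        raise ValueError("metric must be 'TD' or 'PD'")
    if threshold not in _THRESHOLD_TO_CATEGORY:
        raise ValueError("threshold must be one of 5, 2, 1 (percent)")
    probs = exam.td_prob if metric == "TD" else exam.pd_prob
    return np.asarray(probs, dtype=int) >= int(_THRESHOLD_TO_CATEGORY[threshold])


def estimated_field_from_presence(
    presence: Sequence[bool] | np.ndarray,
    laterality: Laterality | str = Laterality.OD,
) -> EstimatedField:
    """Turn fundus-space presence calls into a field-space defect map.

    Defect is the negation of NFB presence.  Because presence calls are
    indexed by the source field point (``RetinalPoint.source_index``), the
    upside-down flip back to visual-field orientation is the exact inverse
    of the forward projection and reduces to index bookkeeping; the
    laterality argument documents which mirror convention produced the
    calls.
    """
    Laterality(laterality)
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != (N_POINTS,):
        raise ValueError(f"presence must have {N_POINTS} entries")
    return EstimatedField(defect=~presence)


def confusion(
    est: EstimatedField, actual_flags: Sequence[bool] | np.ndarray
) -> ConfusionCounts:
    """2x2 confusion counts between estimated and actual defect maps."""
    actual = np.asarray(actual_flags, dtype=bool)
    if actual.shape != est.defect.shape:
        raise ValueError("estimated and actual fields differ in length")
    e = est.defect
    return ConfusionCounts(
        positive=int(np.sum(e & actual)),
        negative=int(np.sum(~e & ~actual)),
        false_positive=int(np.sum(e & ~actual)),
        false_negative=int(np.sum(~e & actual)),
    )


def accuracy_pct(c: ConfusionCounts) -> float:
    """Percent of points judged concordantly: (pos + neg) / n x 100."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    return (c.positive + c.negative) / c.total * 100.0


def kappa_from_cells(
    positive: float, negative: float, false_positive: float, false_negative: float
) -> float:
    """Cohen's kappa from the four agreement cells (float-friendly core).

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the marginals.  Returns NaN when
    p_e = 1 (a degenerate single-class table), where kappa is undefined.
    """
    n = positive + negative + false_positive + false_negative
    if n <= 0:
        raise ValueError("empty confusion table")
    p_o = (positive + negative) / n
    est_defect = (positive + false_positive) / n
    act_defect = (positive + false_negative) / n
    p_e = est_defect * act_defect + (1 - est_defect) * (1 - act_defect)
    if np.isclose(p_e, 1.0):
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def cohens_kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa of a confusion table; NaN for degenerate tables."""
    return kappa_from_cells(
        c.positive, c.negative, c.false_positive, c.false_negative
    )


def cluster_accuracy(
    est: EstimatedField,
    actual_flags: Sequence[bool] | np.ndarray,
    grid: FieldGrid,
) -> dict[str, float]:
    """Accuracy restricted to each cluster, denominator = cluster size."""
    actual = np.asarray(actual_flags, dtype=bool)
    agree = est.defect == actual
    out: dict[str, float] = {}
    for name in ("C1", "C2", "C3"):
        idx = np.array(grid.cluster_indices(name), dtype=int)
        if idx.size == 0:
            out[name] = float("nan")
        else:
            out[name] = float(np.mean(agree[idx]) * 100.0)
    return out


def score_eye(
    est: EstimatedField,
    exam: VisualFieldExam,
    grid: FieldGrid,
    metric: str,
    threshold: int,
) -> ConcordanceResult:
    """All agreement statistics for one eye at one (metric, threshold)."""
    actual = defect_flags(exam, metric, threshold)
    c = confusion(est, actual)
    return ConcordanceResult(
        counts=c,
        accuracy_pct=accuracy_pct(c),
        kappa=cohens_kappa(c),
        cluster_accuracy=cluster_accuracy(est, actual, grid),
        metric=metric.upper(),
        threshold=threshold,
    )


HIGH_MYOPIA_CUTOFF_D = -6.0


def myopia_group(spherical_equivalent: float) -> str:
    """'high' iff SE < -6 D (strict); -6.0 D itself is non-high."""
    return "high" if spherical_equivalent < HIGH_MYOPIA_CUTOFF_D else "non_high"


def cohort_summary(
    results: Mapping[str, Mapping[tuple[str, int], ConcordanceResult]],
    spherical_equivalents: Mapping[str, float],
) -> pd.DataFrame:
    """Cohort means of kappa and accuracy, total and by myopia group.

    ``results`` maps eye id -> {(metric, threshold): ConcordanceResult}.
    Rows: total / non-high myopia (SE >= -6 D) / high myopia (SE < -6 D);
    columns: one per (metric, threshold) cell, mean kappa and accuracy.
    Undefined (NaN) kappas are excluded from the kappa means; their count
    is reported.
    """
    if not results:
        raise ValueError("no eyes to summarise")
    cells = sorted(
        {key for per_eye in results.values() for key in per_eye},
        key=lambda mt: (mt[0], -mt[1]),
    )
    groups = {
        "total": list(results),
        "non_high_myopia": [
            e for e in results if myopia_group(spherical_equivalents[e]) == "non_high"
        ],
        "high_myopia": [
            e for e in results if myopia_group(spherical_equivalents[e]) == "high"
        ],
    }
    rows = []
    for gname, eyes in groups.items():
        row: dict[str, float | int | str] = {"group": gname, "n_eyes": len(eyes)}
        for metric, th in cells:
            kappas = np.array(
                [results[e][(metric, th)].kappa for e in eyes], dtype=float
            )
            accs = np.array(
                [results[e][(metric, th)].accuracy_pct for e in eyes], dtype=float
            )
            tag = f"{metric}_lt{th}"
            defined = ~np.isnan(kappas)
            row[f"kappa_{tag}"] = (
                float(np.mean(kappas[defined])) if defined.any() else float("nan")
            )
            row[f"accuracy_{tag}"] = (
                float(np.mean(accs)) if len(eyes) else float("nan")
            )
            row[f"n_undefined_kappa_{tag}"] = int(np.sum(~defined))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def cluster_summary(
    results: Mapping[str, Mapping[tuple[str, int], ConcordanceResult]],
) -> pd.DataFrame:
    """Cohort-mean cluster accuracies per (metric, threshold) cell."""
    cells = sorted(
        {key for per_eye in results.values() for key in per_eye},
        key=lambda mt: (mt[0], -mt[1]),
    )
    rows = []
    for metric, th in cells:
        row: dict[str, float | str | int] = {"metric": metric, "threshold": th}
        for cname in ("C1", "C2", "C3"):
            vals = [
                res[(metric, th)].cluster_accuracy[cname]
                for res in results.values()
            ]
            row[f"accuracy_{cname}"] = float(np.nanmean(np.asarray(vals)))
        rows.append(row)
    return pd.DataFrame(rows)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample ``a`` with midrank tie handling."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = float(np.sum(ranks[: a.size]))
    return r_a - a.size * (a.size + 1) / 2.0


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 8
) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of group assignments (midrank ties
    included) when min(n1, n2) <= ``exact_max_n``; otherwise the normal
    approximation with tie correction via scipy.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(a, b)
    if min(a.size, b.size) <= exact_max_n:
        combined = np.concatenate([a, b])
        n1 = a.size
        mid = a.size * b.size / 2.0
        dev_obs = abs(u_obs - mid)
        count = 0
        total = 0
        for pick in itertools.combinations(range(combined.size), n1):
            mask = np.zeros(combined.size, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(combined[mask], combined[~mask])
            # tolerance guards float midranks
            if abs(u - mid) >= dev_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return {"U": float(u_obs), "p_two_sided": float(min(p, 1.0))}
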