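"""End-to-end orchestration: image -> presence calls -> concordance report.

Small glue layer used both by the command-line interface and directly in
analyses: judge every mapped test point on a case's en-face image, build
the estimated field, score it against the exam at each (metric, threshold)
cell, and aggregate a cohort with the reliability filter applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import concordance as cc
from .concordance import (
    ConcordanceResult,
    EstimatedField,
    VisualFieldExam,
    check_reliability,
    estimated_field_from_presence,
    score_eye,
)
from .judgement import JudgementParams, JudgementResult, judge_all
from .mapping import (
    FieldGrid,
    MappingConfig,
    assign_clusters,
    build_grid_10_2,
    map_grid,
)
from .synthetic import SyntheticCase

METRICS = ("TD", "PD")
THRESHOLDS = (5, 2, 1)


def default_grid(c1_mask=None) -> FieldGrid:
    """The 68-point grid with clusters assigned."""
    return assign_clusters(build_grid_10_2(), c1_mask)


def estimate_case(
    case: SyntheticCase,
    mapping_cfg: MappingConfig | None = None,
    params: JudgementParams | None = None,
) -> JudgementResult:
    """NFB presence calls for one case's en-face image."""
    if case.image is None:
        raise ValueError("case carries no image; regenerate with render_image")
    grid = build_grid_10_2()
    pts = map_grid(grid, case.laterality, mapping_cfg, displace=True)
    return judge_all(case.image, pts, params)


def score_case(
    presence: Sequence[bool] | np.ndarray,
    exam: VisualFieldExam,
    grid: FieldGrid,
    metrics: Sequence[str] = METRICS,
    thresholds: Sequence[int] = THRESHOLDS,
) -> dict[tuple[str, int], ConcordanceResult]:
    """Score one eye's presence calls at every (metric, threshold) cell."""
    est = estimated_field_from_presence(presence, exam.laterality)
    return {
        (m, t): score_eye(est, exam, grid, m, t)
        for m in metrics
        for t in thresholds
    }


@dataclass
class CohortReport:
    """Per-eye results plus cohort summary tables and the exclusion log."""

    per_eye: dict[str, dict[tuple[str, int], ConcordanceResult]]
    spherical_equivalents: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)

    def summary(self):
        return cc.cohort_summary(self.per_eye, self.spherical_equivalents)

    def cluster_table(self):
        return cc.cluster_summary(self.per_eye)


def run_cohort(
    cases: Sequence[SyntheticCase],
    mapping_cfg: MappingConfig | None = None,
    params: JudgementParams | None = None,
    metrics: Sequence[str] = METRICS,
    thresholds: Sequence[int] = THRESHOLDS,
    use_structural_truth: bool = False,
    c1_mask=None,
) -> CohortReport:
    """Run the full pipeline over a cohort with the reliability filter.

    ``use_structural_truth`` bypasses the image reader and scores the
    generator's structural truth directly (the perfect-classification
    limit, useful for studying the discordance model in isolation).
    """
    grid = default_grid(c1_mask)
    per_eye: dict[str, dict[tuple[str, int], ConcordanceResult]] = {}
    ses: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for i, case in enumerate(cases):
        eye_id = f"eye{i:03d}"
        if not check_reliability(case.exam):
            excluded[eye_id] = "unreliable exam (fixation loss / FP / FN)"
            continue
        if use_structural_truth:
            presence = ~np.asarray(case.truth_structural, dtype=bool)
        else:
            presence = estimate_case(case, mapping_cfg, params).presence
        per_eye[eye_id] = score_case(presence, case.exam, grid, metrics, thresholds)
        ses[eye_id] = case.spherical_equivalent
    return CohortReport(per_eye=per_eye, spherical_equivalents=ses, excluded=excluded)


def expected_confusion(
    n_defects: int, q: float, n_points: int = cc.N_POINTS
) -> tuple[float, float, float, float]:
    """Expected (pos, neg, FP, FN) cells under the discordance model.

    With perfect structural classification and per-point functional flags
    equal to structure XOR Bernoulli(q): an eye with k structural defects
    has expected cells (k(1-q), (n-k)(1-q), kq, (n-k)q) — false cells are
    exactly the flipped points.
    """
    k = float(n_defects)
    n = float(n_points)
    return (k * (1 - q), (n - k) * (1 - q), k * q, (n - k) * q)


def expected_kappa(n_defects: int, q: float, n_points: int = cc.N_POINTS) -> float:
    """Cohen's kappa of the expected confusion table under the q-model."""
    pos, neg, fp, fn = expected_confusion(n_defects, q, n_points)
    return cc.kappa_from_cells(pos, neg, fp, fn)
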