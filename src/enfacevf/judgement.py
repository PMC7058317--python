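"""Nerve-fiber-bundle presence calls at mapped test points.

In the clinical workflow presence/absence of NFBs at each test point is a
human judgement made by several masked examiners and settled by majority
vote.  Here an automated reader takes that role: each point is judged by
windowed binarisation of the en-face reflectance (fraction of non-vessel
pixels above a global threshold), and a multi-grader simulator reproduces
the majority-vote structure so agreement statistics (ICC) can be studied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .enface import EnFaceImage
from .mapping import RetinalPoint


@dataclass(frozen=True)
class JudgementParams:
    """Parameters of the automated presence classifier.

    ``window_radius_mm`` is roughly half the 2-degree point spacing after
    degree-to-mm conversion, so neighbouring windows do not overlap.
    ``threshold_mode`` is either a global Otsu threshold on the non-vessel
    histogram (scale-free default) or a fixed fraction of the median
    background level.  A point is called *present* when at least
    ``min_present_fraction`` of its non-vessel window pixels exceed the
    threshold.  Windows fully covered by vessels or outside the image are
    indeterminate and resolved by ``indeterminate_as_present``
    (conservative default: present).
    """

    window_radius_mm: float = 0.15
    threshold_mode: str = "otsu_global"
    threshold_value: float = 0.5
    min_present_fraction: float = 0.25
    exclude_vessels: bool = True
    indeterminate_as_present: bool = True

    def __post_init__(self) -> None:
        if self.window_radius_mm <= 0:
            raise ValueError("window_radius_mm must be positive")
        if not (0 < self.min_present_fraction <= 1):
            raise ValueError("min_present_fraction must be in (0, 1]")
        if self.threshold_mode not in ("otsu_global", "fraction_of_background"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass(frozen=True)
class PointJudgement:
    """Per-grader presence calls and their majority-vote consensus."""

    source_index: int
    per_grader: tuple[bool, ...]
    consensus: bool

    def __post_init__(self) -> None:
        if len(self.per_grader) % 2 == 1:
            expected = sum(self.per_grader) * 2 > len(self.per_grader)
            if self.consensus != expected:
                raise ValueError("consensus must equal strict majority")


@dataclass
class JudgementResult:
    """Presence vector aligned with grid indices plus indeterminate flags."""

    presence: np.ndarray
    indeterminate: tuple[int, ...] = ()


def compute_threshold(img: EnFaceImage, params: JudgementParams) -> float:
    """Global binarisation threshold for the whole mosaic."""
    vals = img.intensity
    if params.exclude_vessels and img.vessel_mask is not None:
        vals = vals[~img.vessel_mask]
    vals = np.asarray(vals, dtype=float).ravel()
    if vals.size == 0:
        return 0.0  # fully vessel-masked mosaic: windows are indeterminate
    if params.threshold_mode == "otsu_global":
        if np.ptp(vals) == 0:
            # constant image: cut just below the single level so every
            # window reads present rather than absent
            v = float(vals[0])
            return v - 1e-9 * max(abs(v), 1.0)
        t = float(threshold_otsu(vals))
        # refine to the midpoint of the two class means (one isodata step):
        # Otsu's argmax is resolved at bin granularity and on a plateau it
        # returns the lowest candidate, which can sit flush against the
        # dark mode instead of mid-gap
        for _ in range(8):
            below = vals[vals <= t]
            above = vals[vals > t]
            if not (below.size and above.size):
                break
            t_new = 0.5 * (float(below.mean()) + float(above.mean()))
            if abs(t_new - t) < 1e-9:
                break
            t = t_new
        return t
    return params.threshold_value * float(np.median(vals))


def _window_values(
    img: EnFaceImage, pt: RetinalPoint, params: JudgementParams
) -> np.ndarray | None:
    """Non-vessel intensities in the disc-shaped window around ``pt``.

    Returns None when the window lies outside the image or is fully
    vessel-masked (indeterminate).
    """
    h, w = img.intensity.shape
    fx, fy = img.fovea_xy
    # fundus-frame y_mm points up; image rows grow downward
    cx = fx + pt.x_mm / img.mm_per_pixel
    cy = fy - pt.y_mm / img.mm_per_pixel
    r_px = params.window_radius_mm / img.mm_per_pixel
    x0, x1 = int(np.floor(cx - r_px)), int(np.ceil(cx + r_px))
    y0, y1 = int(np.floor(cy - r_px)), int(np.ceil(cy + r_px))
    if x1 < 0 or y1 < 0 or x0 >= w or y0 >= h:
        return None
    xs = np.arange(max(x0, 0), min(x1, w - 1) + 1)
    ys = np.arange(max(y0, 0), min(y1, h - 1) + 1)
    if xs.size == 0 or ys.size == 0:
        return None
    xx, yy = np.meshgrid(xs, ys)
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    if not inside.any():
        return None
    if params.exclude_vessels and img.vessel_mask is not None:
        inside &= ~img.vessel_mask[yy, xx]
        if not inside.any():
            return None
    return img.intensity[yy[inside], xx[inside]]


def judge_point(
    img: EnFaceImage,
    pt: RetinalPoint,
    params: JudgementParams | None = None,
    threshold: float | None = None,
) -> bool | None:
    """Presence call at one point; None marks an indeterminate window."""
    params = params or JudgementParams()
    if threshold is None:
        threshold = compute_threshold(img, params)
    vals = _window_values(img, pt, params)
    if vals is None:
        return None
    frac = float(np.mean(vals > threshold))
    return frac >= params.min_present_fraction


def judge_all(
    img: EnFaceImage,
    points: Sequence[RetinalPoint],
    params: JudgementParams | None = None,
) -> JudgementResult:
    """Presence calls for all mapped points, ordered by source_index.

    The global threshold is computed once for the mosaic and shared by all
    windows.  Indeterminate points are resolved by the configured policy
    and reported in ``indeterminate``.
    """
    params = params or JudgementParams()
    threshold = compute_threshold(img, params)
    n = len(points)
    presence = np.zeros(n, dtype=bool)
    indeterminate: list[int] = []
    for pt in sorted(points, key=lambda p: p.source_index):
        call = judge_point(img, pt, params, threshold)
        if call is None:
            indeterminate.append(pt.source_index)
            call = params.indeterminate_as_present
        presence[pt.source_index] = call
    return JudgementResult(presence=presence, indeterminate=tuple(indeterminate))


def simulate_graders(
    truth: Sequence[bool] | np.ndarray,
    flip_prob: float,
    n_graders: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[PointJudgement]:
    """Simulate masked examiners as independent bit-flips of the truth.

    Each grader misreads each point independently with probability
    ``flip_prob``; consensus is the strict majority vote, mirroring the
    three-examiner protocol.
    """
    if not (0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must be in [0, 0.5)")
    if n_graders % 2 == 0 or n_graders < 1:
        raise ValueError("n_graders must be odd and positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    truth = np.asarray(truth, dtype=bool)
    flips = rng.random((truth.size, n_graders)) < flip_prob
    ratings = truth[:, None] ^ flips
    out = []
    for i in range(truth.size):
        votes = tuple(bool(v) for v in ratings[i])
        out.append(
            PointJudgement(
                source_index=i,
                per_grader=votes,
                consensus=sum(votes) * 2 > n_graders,
            )
        )
    return out


def majority_error_prob(flip_prob: float, n_graders: int = 3) -> float:
    """Closed-form probability that the majority vote is wrong.

    For i.i.d. per-grader error p, the majority errs when more than half of
    the graders err; for n = 3 this is 3 p^2 (1 - p) + p^3.
    """
    from math import comb

    p = flip_prob
    k_min = n_graders // 2 + 1
    return float(
        sum(
            comb(n_graders, k) * p**k * (1 - p) ** (n_graders - k)
            for k in range(k_min, n_graders + 1)
        )
    )


def intergrader_icc(judgements: Sequence[PointJudgement]) -> float:
    """Two-way ICC(A,1): absolute agreement, single rater, on 0/1 ratings.

    Rows are test points (random targets), columns are graders.  Computed
    from the standard two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    Returns NaN when the ratings carry no between-point variance (the
    coefficient is undefined, not zero).
    """
    ratings = np.array(
        [[float(v) for v in j.per_grader] for j in judgements], dtype=float
    )
    n, k = ratings.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 graders and >= 2 points")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((ratings - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    # snap round-off dust to zero so duplicated raters give exactly 1
    tol = 1e-12 * max(ss_total, 1.0)
    ss_cols = 0.0 if ss_cols < tol else ss_cols
    ss_err = 0.0 if ss_err < tol else ss_err
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)
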