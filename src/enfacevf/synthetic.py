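"""Synthetic POAG eyes: en-face images paired with 10-2 exams.

The generator emulates the clinical material end to end: a wide-field en-face
reflectance mosaic (bright striated nerve fiber bundles, dark arcuate
wedge defects fanning out from the optic disc, dark vessels, additive
noise) together with a matching 10-2 exam whose probability-plot flags
agree with the structural truth up to a programmable discordance rate q.

Fiber geometry
--------------
Bundles follow non-crossing arcs from the disc that respect the temporal
horizontal raphe.  Each arc is labelled by its disc entry angle theta0;
a retinal point maps to the bundle coordinate

    theta0(p) = phi(p) / (1 + beta * r(p))

where phi is the angle of p about the disc (zero toward the fovea,
positive superior) and r the distance from the disc in mm.  Level sets of
theta0 are the arcs; an arcuate defect is an interval [lo, hi] in theta0.
The sign of theta0 equals the sign of phi, so no arc crosses the raphe.

Structural truth
----------------
A test point's NFB-absent flag is decided at the judgement aperture: the
point is a structural defect when the defect wedges cover more than 75% of
its judgement window (the complement of the automated reader's 25%
bright-fraction presence rule).  Wedge boundaries are resampled until no
window coverage falls in the ambiguous middle band, so in the noise-free
limit the automated reader reproduces the structural truth exactly.
Functional truth is structural truth XOR Bernoulli(q) per point, and exam
categories are drawn consistently with the functional truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .concordance import ProbCategory, VisualFieldExam
from .enface import EnFaceImage, OCTVolume
from .judgement import JudgementParams
from .mapping import (
    FieldGrid,
    Laterality,
    MappingConfig,
    build_grid_10_2,
    map_grid,
)

#: Disc centre distance from the fovea along the horizontal raphe, mm.
DISC_DISTANCE_MM = 4.32
#: Arc curvature parameter of the bundle coordinate (1/mm).
FIBER_BETA = 0.12


@dataclass(frozen=True)
class Wedge:
    """An arcuate defect: a theta0 interval (radians), lo < hi."""

    lo: float
    hi: float

    def contains(self, theta0: np.ndarray) -> np.ndarray:
        return (theta0 >= self.lo) & (theta0 <= self.hi)


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort-level generator settings.

    Defaults emulate a POAG reading-study cohort: 38 eyes spanning early to advanced
    damage (structural defect counts between 5 and 60 of the 68 points),
    predominantly superior-field (inferior-retina) arcuate defects with
    papillomacular sparing, spherical equivalent drawn from
    N(-4.3, 4.0) dB truncated to the observed range (about a third of eyes
    fall below the -6 D high-myopia cutoff), and a per-point
    structure-function discordance probability of 0.1 — the order implied
    by the reported ~88% point-wise agreement.
    """

    n_eyes: int = 38
    seed: int = 0
    laterality_mix: float = 0.5  # probability of OD
    n_wedges_range: tuple[int, int] = (1, 2)
    wedge_extent_rad: tuple[float, float] = (0.25, 0.70)
    wedge_depth: float = 0.85
    superior_field_bias: float = 0.7
    papillomacular_sparing: bool = True
    diffuse_loss_fraction: float = 0.0
    discordance_prob: float = 0.1
    noise_sd: float = 0.02
    n_vessels: int = 6
    se_mean: float = -4.3
    se_sd: float = 4.0
    se_range: tuple[float, float] = (-11.375, 2.625)
    p_mild_abnormal: float = 0.0  # chance a normal point prints <5%
    defect_count_range: tuple[int, int] = (5, 60)
    reliability_failure_prob: float = 0.0
    mm_per_pixel: float = 0.03
    render_image: bool = True
    mapping: MappingConfig = field(default_factory=MappingConfig)
    judgement: JudgementParams = field(default_factory=JudgementParams)

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if not (0 <= self.discordance_prob < 0.5):
            raise ValueError("discordance_prob must be in [0, 0.5)")
        for p in (
            self.laterality_mix,
            self.superior_field_bias,
            self.p_mild_abnormal,
            self.reliability_failure_prob,
        ):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SyntheticCase:
    """One simulated eye: image, exam, and the two ground truths."""

    exam: VisualFieldExam
    truth_structural: np.ndarray  # True = NFB absent
    truth_functional: np.ndarray  # True = field defect
    laterality: Laterality
    spherical_equivalent: float
    eye_seed: int
    image: EnFaceImage | None = None
    wedges: tuple[Wedge, ...] = ()


def _disc_center_mm(laterality: Laterality) -> tuple[float, float]:
    sign = 1.0 if laterality is Laterality.OD else -1.0
    return (sign * DISC_DISTANCE_MM, 0.0)


def bundle_coordinate(
    x_mm: np.ndarray,
    y_mm: np.ndarray,
    laterality: Laterality,
    beta: float = FIBER_BETA,
) -> tuple[np.ndarray, np.ndarray]:
    """(theta0, r_disc) of fundus-frame points for the given eye."""
    dx, dy = _disc_center_mm(laterality)
    vx = np.asarray(x_mm, dtype=float) - dx
    vy = np.asarray(y_mm, dtype=float) - dy
    toward_fovea = -vx if laterality is Laterality.OD else vx
    phi = np.arctan2(vy, toward_fovea)
    r = np.hypot(vx, vy)
    theta0 = phi / (1.0 + beta * r)
    return theta0, r


def fiber_trajectories(
    laterality: Laterality | str,
    theta0s: Sequence[float] | None = None,
    r_max: float = 8.0,
    beta: float = FIBER_BETA,
) -> list[np.ndarray]:
    """Sampled bundle arcs (each an (N, 2) array of fundus mm coordinates).

    Arcs leave the disc at angle theta0 and bend away as
    phi(r) = theta0 (1 + beta r); they never cross one another and never
    cross the temporal horizontal raphe.
    """
    lat = Laterality(laterality)
    dx, dy = _disc_center_mm(lat)
    sx = -1.0 if lat is Laterality.OD else 1.0  # toward the fovea
    if theta0s is None:
        # keep |theta0| (1 + beta r_max) < pi so the disc-polar angle never
        # wraps and the bundle coordinate stays invertible along each arc
        theta0s = np.linspace(-1.55, 1.55, 25)
    rr = np.linspace(0.3, r_max, 200)
    arcs = []
    for t0 in theta0s:
        phi = t0 * (1.0 + beta * rr)
        xs = dx + rr * sx * np.cos(phi)
        ys = dy + rr * np.sin(phi)
        arcs.append(np.column_stack([xs, ys]))
    return arcs


@dataclass
class _EyeGeometry:
    """Canvas geometry shared by truth computation and rendering."""

    laterality: Laterality
    mm_per_pixel: float
    h: int
    w: int
    fovea_col: float
    fovea_row: float
    theta0: np.ndarray  # per-pixel bundle coordinate
    vessel_mask: np.ndarray


def _make_geometry(
    rng: np.random.Generator, spec: SyntheticSpec, laterality: Laterality
) -> _EyeGeometry:
    """Set up the mosaic canvas, bundle-coordinate map and vessel mask.

    The 9 x 6 mm canvas covers the whole (displaced) 10-2 grid around the
    fovea plus the optic disc.  Vessels are sampled here, before the
    defect wedges, because the structural truth at each test point is
    evaluated on the same vessel-excluded pixel windows the automated
    reader uses.
    """
    mmpp = spec.mm_per_pixel
    h, w = 200, 300
    fovea_col = 106 if laterality is Laterality.OD else w - 1 - 106
    fovea_row = h // 2
    x_mm = (np.arange(w)[None, :] - fovea_col) * mmpp
    y_mm = (fovea_row - np.arange(h)[:, None]) * mmpp
    X = np.broadcast_to(x_mm, (h, w))
    Y = np.broadcast_to(y_mm, (h, w))
    theta0, _ = bundle_coordinate(X, Y, laterality)

    vmask = np.zeros((h, w), dtype=bool)
    dxy = _disc_center_mm(laterality)
    sx = -1.0 if laterality is Laterality.OD else 1.0
    vessel_t0 = rng.uniform(0.25, 1.3, size=spec.n_vessels) * rng.choice(
        [-1.0, 1.0], size=spec.n_vessels
    )
    rr = np.arange(0.3, 8.0, mmpp / 2)
    for t0 in vessel_t0:
        phi = t0 * (1.0 + FIBER_BETA * rr)
        vx = dxy[0] + rr * sx * np.cos(phi)
        vy = dxy[1] + rr * np.sin(phi)
        cc = np.round(fovea_col + vx / mmpp).astype(int)
        rw = np.round(fovea_row - vy / mmpp).astype(int)
        ok = (cc >= 0) & (cc < w) & (rw >= 0) & (rw < h)
        vmask[rw[ok], cc[ok]] = True
    vmask = binary_dilation(vmask, iterations=1)
    return _EyeGeometry(
        laterality=laterality,
        mm_per_pixel=mmpp,
        h=h,
        w=w,
        fovea_col=float(fovea_col),
        fovea_row=float(fovea_row),
        theta0=theta0,
        vessel_mask=vmask,
    )


def _defect_map(geo: _EyeGeometry, wedges: Sequence[Wedge]) -> np.ndarray:
    defect = np.zeros((geo.h, geo.w), dtype=bool)
    for wd in wedges:
        defect |= wd.contains(geo.theta0)
    return defect


def _bright_fractions(
    geo: _EyeGeometry,
    wedges: Sequence[Wedge],
    mapped_xy: np.ndarray,
    params: JudgementParams,
) -> np.ndarray:
    """Per-point bright-pixel fraction of a noise-free defect indicator.

    Uses the reader's own window machinery (same pixel footprint, same
    vessel exclusion), so thresholding these fractions at
    ``min_present_fraction`` is exactly what the reader computes in the
    noise-free limit.  NaN marks an indeterminate window.
    """
    from .judgement import _window_values
    from .mapping import RetinalPoint

    indicator = EnFaceImage(
        intensity=(~_defect_map(geo, wedges)).astype(float),
        mm_per_pixel=geo.mm_per_pixel,
        fovea_xy=(geo.fovea_col, geo.fovea_row),
        laterality=geo.laterality,
        vessel_mask=geo.vessel_mask,
    )
    fracs = np.empty(mapped_xy.shape[0])
    for i, (x, y) in enumerate(mapped_xy):
        pt = RetinalPoint(x_mm=x, y_mm=y, displaced=True, source_index=i)
        vals = _window_values(indicator, pt, params)
        fracs[i] = np.nan if vals is None else float(np.mean(vals > 0.5))
    return fracs


#: Half-width of the ambiguous bright-fraction band around the reader's
#: decision boundary within which wedge placements are rejected.
_AMBIGUITY_BAND = 0.10


def _sample_wedges(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    geo: _EyeGeometry,
    mapped_xy: np.ndarray,
    max_tries: int = 400,
) -> tuple[tuple[Wedge, ...], np.ndarray]:
    """Draw defect wedges yielding unambiguous structural truth.

    A placement is accepted when no test-point window has a bright
    fraction within ``_AMBIGUITY_BAND`` of the presence threshold and the
    structural defect count falls in the configured range; the truth flag
    is then the reader's own decision rule evaluated noise-free.
    Indeterminate (vessel-covered) windows default to present.
    """
    theta_min = 0.10 if spec.papillomacular_sparing else 0.02
    lo_n, hi_n = spec.n_wedges_range
    lo_c, hi_c = spec.defect_count_range
    cut = spec.judgement.min_present_fraction
    for _ in range(max_tries):
        n_w = int(rng.integers(lo_n, hi_n + 1))
        wedges = []
        for _ in range(n_w):
            sign = -1.0 if rng.random() < spec.superior_field_bias else 1.0
            center = rng.uniform(theta_min + 0.08, 0.75)
            ext = rng.uniform(*spec.wedge_extent_rad)
            lo_t = max(center - ext / 2, theta_min)
            hi_t = center + ext / 2
            a, b = sorted((sign * lo_t, sign * hi_t))
            wedges.append(Wedge(lo=a, hi=b))
        fracs = _bright_fractions(geo, wedges, mapped_xy, spec.judgement)
        defined = ~np.isnan(fracs)
        if np.any(np.abs(fracs[defined] - cut) <= _AMBIGUITY_BAND):
            continue
        truth = np.where(defined, fracs < cut, False)
        if lo_c <= int(truth.sum()) <= hi_c:
            return tuple(wedges), truth.astype(bool)
    raise RuntimeError(
        "could not place defect wedges with unambiguous coverage; "
        "relax defect_count_range or wedge geometry"
    )


def _render_image(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    geo: _EyeGeometry,
    wedges: Sequence[Wedge],
) -> EnFaceImage:
    """Render the en-face mosaic for one eye on its prepared geometry."""
    n_bundles = rng.uniform(80, 100)
    phase = rng.uniform(0, 2 * np.pi)
    # mild stripe modulation keeps the healthy reflectance mode compact so
    # global binarisation separates defect from texture, not texture phases
    stripes = 0.85 + 0.15 * np.cos(geo.theta0 * n_bundles + phase)
    img = 0.8 * stripes
    img = np.where(_defect_map(geo, wedges), img * (1.0 - spec.wedge_depth), img)
    img *= 1.0 - spec.diffuse_loss_fraction
    img = np.where(geo.vessel_mask, img * 0.15, img)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.2)

    dxy = _disc_center_mm(geo.laterality)
    disc_col = geo.fovea_col + dxy[0] / geo.mm_per_pixel
    disc_row = geo.fovea_row - dxy[1] / geo.mm_per_pixel
    return EnFaceImage(
        intensity=img,
        mm_per_pixel=geo.mm_per_pixel,
        fovea_xy=(geo.fovea_col, geo.fovea_row),
        disc_xy=(float(disc_col), float(disc_row)),
        laterality=geo.laterality,
        vessel_mask=geo.vessel_mask,
    )


def _draw_categories(
    rng: np.random.Generator, flags: np.ndarray, p_mild: float
) -> np.ndarray:
    """Probability-plot categories consistent with the defect flags.

    Defect points print deep categories (<1% or <0.5%); normal points
    print normal, with an optional chance of a mild <5% flag.
    """
    n = flags.size
    cats = np.full(n, int(ProbCategory.NORMAL))
    deep = np.where(
        rng.random(n) < 0.6, int(ProbCategory.P1), int(ProbCategory.P05)
    )
    cats[flags] = deep[flags]
    mild = (~flags) & (rng.random(n) < p_mild)
    cats[mild] = int(ProbCategory.P5)
    return cats


def _make_exam(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    truth_functional: np.ndarray,
    grid: FieldGrid,
    laterality: Laterality,
    se: float,
) -> VisualFieldExam:
    flags = truth_functional
    td = np.where(
        flags, rng.normal(-18.0, 4.0, flags.size), rng.normal(-1.0, 1.5, flags.size)
    )
    pd_db = td + 1.0  # pattern deviation: general depression removed
    ecc = np.array([p.eccentricity_deg for p in grid])
    sens = np.clip(32.0 - 0.3 * ecc + td, 0.0, None)
    if rng.random() < spec.reliability_failure_prob:
        fl = rng.uniform(0.25, 0.5)
    else:
        fl = rng.uniform(0.0, 0.20)
    return VisualFieldExam(
        sensitivity_db=sens,
        td_db=td,
        pd_db=pd_db,
        td_prob=_draw_categories(rng, flags, spec.p_mild_abnormal),
        pd_prob=_draw_categories(rng, flags, spec.p_mild_abnormal),
        fixation_loss_rate=float(fl),
        false_pos_rate=float(rng.uniform(0.0, 0.15)),
        false_neg_rate=float(rng.uniform(0.0, 0.28)),
        md_10_2=float(td.mean()),
        spherical_equivalent=se,
        laterality=laterality,
    )


def render_eye(spec: SyntheticSpec, eye_seed: int) -> SyntheticCase:
    """Generate one synthetic eye, bitwise reproducible from its seed."""
    rng = np.random.default_rng(eye_seed)
    laterality = (
        Laterality.OD if rng.random() < spec.laterality_mix else Laterality.OS
    )
    se = float(
        np.clip(rng.normal(spec.se_mean, spec.se_sd), *spec.se_range)
    )
    grid = build_grid_10_2()
    mapped = map_grid(grid, laterality, spec.mapping, displace=True)
    mapped_xy = np.array(
        [(r.x_mm, r.y_mm) for r in sorted(mapped, key=lambda r: r.source_index)]
    )
    geo = _make_geometry(rng, spec, laterality)
    wedges, truth_structural = _sample_wedges(rng, spec, geo, mapped_xy)
    flips = rng.random(truth_structural.size) < spec.discordance_prob
    truth_functional = truth_structural ^ flips
    exam = _make_exam(rng, spec, truth_functional, grid, laterality, se)
    image = _render_image(rng, spec, geo, wedges) if spec.render_image else None
    return SyntheticCase(
        exam=exam,
        truth_structural=truth_structural,
        truth_functional=truth_functional,
        laterality=laterality,
        spherical_equivalent=se,
        eye_seed=int(eye_seed),
        image=image,
        wedges=wedges,
    )


def generate_cohort(spec: SyntheticSpec) -> list[SyntheticCase]:
    """Generate ``spec.n_eyes`` independent eyes from the master seed."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_eyes)
    return [
        render_eye(spec, int(child.generate_state(1)[0] % 2**31))
        for child in children
    ]


def make_volume_from_image(
    img: EnFaceImage,
    depth_px: int = 32,
    bundle_depth_px: int = 4,
    um_per_pixel_z: float = 10.0,
    ilm_tilt_px: int = 0,
    rng: np.random.Generator | None = None,
) -> OCTVolume:
    """Embed an en-face raster into a small synthetic OCT cube.

    The raster becomes a reflective band ``bundle_depth_px`` below a
    (optionally tilted) ILM surface, over a dim background — enough
    structure to exercise ILM flattening, slab extraction and slab-depth
    selection without modelling real OCT speckle.
    """
    h, w = img.intensity.shape
    cols = np.arange(w)
    ilm = np.clip(
        (cols[None, :] * ilm_tilt_px) // max(w - 1, 1), 0, depth_px - 1
    ) * np.ones((h, 1), dtype=int)
    vol = np.full((h, w, depth_px), 0.05)
    if rng is not None:
        vol = vol + rng.normal(0, 0.01, size=vol.shape)
    z = ilm + bundle_depth_px
    if (z >= depth_px).any():
        raise ValueError("bundle plane exceeds volume depth under ILM tilt")
    np.put_along_axis(vol, z[..., None], img.intensity[..., None], axis=2)
    return OCTVolume(
        intensity=np.clip(vol, 0.0, None),
        mm_per_pixel_xy=img.mm_per_pixel,
        um_per_pixel_z=um_per_pixel_z,
        ilm_surface=ilm,
        fovea_xy=img.fovea_xy,
        disc_xy=img.disc_xy,
        laterality=Laterality(img.laterality),
    )
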