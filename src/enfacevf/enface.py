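"""En-face image extraction, tile registration and normalisation.

A wide-field reflectance view of the retinal nerve fiber layer is built in
four steps: flatten the OCT volume to the inner limiting membrane (ILM),
project a slab (or single plane) at a chosen depth below the ILM, register
the macular and optic-disc tiles into one mosaic using the large blood
vessels as landmarks, and normalise brightness/contrast/gamma.  All steps
are deterministic re-specifications of what is usually done interactively
in vendor software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .mapping import Laterality

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Raised when the macula/disc tiles cannot be superimposed."""


@dataclass
class OCTVolume:
    """A cube scan: ``intensity[row, col, depth]`` with an ILM surface.

    ``ilm_surface[row, col]`` is the depth index of the ILM for that
    A-scan.  ``mm_per_pixel_xy`` is the transverse scale and
    ``um_per_pixel_z`` the axial scale.  Optional fovea/disc landmarks are
    carried through to extracted en-face images.
    """

    intensity: np.ndarray
    mm_per_pixel_xy: float
    um_per_pixel_z: float
    ilm_surface: np.ndarray
    fovea_xy: tuple[float, float] | None = None
    disc_xy: tuple[float, float] | None = None
    laterality: Laterality | None = None

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be rows x cols x depth")
        if self.ilm_surface.shape != self.intensity.shape[:2]:
            raise ValueError("ilm_surface shape must match transverse grid")


@dataclass
class EnFaceImage:
    """A 2D reflectance raster with fovea/disc landmarks.

    ``fovea_xy`` and ``disc_xy`` are (x, y) pixel coordinates (x = column,
    y = row).  ``vessel_mask`` marks pixels occupied by large blood
    vessels; it is used both for registration and to exclude vessels from
    nerve-fiber-bundle judgement windows.
    """

    intensity: np.ndarray
    mm_per_pixel: float
    fovea_xy: tuple[float, float]
    laterality: Laterality | str = Laterality.OD
    disc_xy: tuple[float, float] | None = None
    vessel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.laterality = Laterality(self.laterality)
        h, w = self.intensity.shape
        fx, fy = self.fovea_xy
        if not (0 <= fx < w and 0 <= fy < h):
            raise ValueError("fovea_xy outside image bounds")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass(frozen=True)
class SlabSpec:
    """Depth window below the ILM, in micrometres.

    ``thickness_um == 0`` selects a single cross-sectional plane, the
    default acquisition style; a positive thickness averages a slab.
    """

    depth_from_ilm_um: float
    thickness_um: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_from_ilm_um < 0 or self.thickness_um < 0:
            raise ValueError("slab depth and thickness must be >= 0")


def flatten_to_ilm(vol: OCTVolume) -> OCTVolume:
    """Shift every A-scan so the ILM sits at depth index 0.

    Pure integer circular shift per A-scan: no interpolation, and the
    multiset of intensities within each A-scan is preserved.
    """
    depth = vol.intensity.shape[2]
    ilm = np.asarray(vol.ilm_surface)
    bad = ~np.isfinite(ilm) | (ilm < 0) | (ilm >= depth)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"missing or out-of-range ILM segment at A-scan (row={r}, col={c})"
        )
    idx = (np.arange(depth)[None, None, :] + ilm[..., None].astype(int)) % depth
    flat = np.take_along_axis(vol.intensity, idx, axis=2)
    return replace(vol, intensity=flat, ilm_surface=np.zeros_like(ilm))


def extract_slab(vol: OCTVolume, spec: SlabSpec) -> EnFaceImage:
    """Mean projection over ``[depth, depth + thickness]`` below the ILM.

    Assumes an ILM-flattened volume.  A zero-thickness spec returns the
    single plane at the requested depth exactly.
    """
    depth = vol.intensity.shape[2]
    d0 = int(round(spec.depth_from_ilm_um / vol.um_per_pixel_z))
    dt = int(round(spec.thickness_um / vol.um_per_pixel_z))
    if d0 + dt >= depth:
        raise ValueError(
            f"slab [{d0}, {d0 + dt}] exceeds volume depth {depth}"
        )
    img = vol.intensity[:, :, d0 : d0 + dt + 1].mean(axis=2)
    h, w = img.shape
    fovea = vol.fovea_xy if vol.fovea_xy is not None else ((w - 1) / 2, (h - 1) / 2)
    return EnFaceImage(
        intensity=img,
        mm_per_pixel=vol.mm_per_pixel_xy,
        fovea_xy=fovea,
        disc_xy=vol.disc_xy,
        laterality=vol.laterality or Laterality.OD,
    )


def _contrast_criterion(img: np.ndarray, vessel_mask: np.ndarray | None) -> float:
    """Coefficient of variation of non-vessel intensity (bundle contrast)."""
    vals = img if vessel_mask is None else img[~vessel_mask]
    m = float(np.mean(vals))
    if m == 0.0:
        return 0.0
    return float(np.std(vals) / m)


def choose_slab_depth(
    vol: OCTVolume,
    candidates: Sequence[SlabSpec],
    vessel_mask: np.ndarray | None = None,
) -> SlabSpec:
    """Pick the candidate slab where bundles are most clearly distinguishable.

    The criterion is the coefficient of variation of slab intensity outside
    the vessel mask — striated bundle/gap texture maximises it.  Ties break
    to the smallest depth.
    """
    if not candidates:
        raise ValueError("need at least one slab candidate")
    ordered = sorted(
        candidates, key=lambda s: (s.depth_from_ilm_um, s.thickness_um)
    )
    best, best_score = None, -np.inf
    for spec in ordered:
        score = _contrast_criterion(extract_slab(vol, spec).intensity, vessel_mask)
        if score > best_score:
            best, best_score = spec, score
    return best


def _ncc_surface(
    a: np.ndarray, b: np.ndarray, min_overlap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised cross-correlation of ``b`` against ``a`` at every shift.

    Linear (zero-padded) correlation with per-shift mean/variance
    normalisation computed from running sums, so the value at each shift is
    the Pearson correlation over the actual overlap region.  Shifts with
    fewer than ``min_overlap`` overlapping pixels are set to -inf.
    """
    a = a.astype(float)
    b = b.astype(float)
    br = b[::-1, ::-1]
    ones_a = np.ones_like(a)
    ones_br = np.ones_like(br)
    n = fftconvolve(ones_a, ones_br, mode="full")
    n = np.maximum(np.round(n), 1.0)
    s_ab = fftconvolve(a, br, mode="full")
    s_a = fftconvolve(a, ones_br, mode="full")
    s_b = fftconvolve(ones_a, br, mode="full")
    s_aa = fftconvolve(a * a, ones_br, mode="full")
    s_bb = fftconvolve(ones_a, (b * b)[::-1, ::-1], mode="full")
    var_a = np.maximum(s_aa - s_a * s_a / n, 0.0)
    var_b = np.maximum(s_bb - s_b * s_b / n, 0.0)
    denom = np.sqrt(var_a * var_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s_ab - s_a * s_b / n) / denom
    r[denom <= 1e-9] = 0.0
    r[n < min_overlap] = -np.inf
    return r, n


def estimate_offset(
    macula: EnFaceImage,
    disc: EnFaceImage,
    min_overlap_frac: float = 0.25,
) -> tuple[int, int, float]:
    """Translation (dx, dy) of the disc tile relative to the macula tile.

    Maximises vessel-mask overlap correlation when both tiles carry vessel
    masks, otherwise normalised cross-correlation of intensities.  Returns
    (dx, dy, correlation at the optimum).
    """
    use_masks = macula.vessel_mask is not None and disc.vessel_mask is not None
    a = macula.vessel_mask.astype(float) if use_masks else macula.intensity
    b = disc.vessel_mask.astype(float) if use_masks else disc.intensity
    min_overlap = int(min_overlap_frac * min(a.size, b.size))
    r, _ = _ncc_surface(a, b, min_overlap)
    if not np.isfinite(r).any():
        raise RegistrationError("tiles share no admissible overlap")
    iy, ix = np.unravel_index(np.argmax(r), r.shape)
    dy = int(iy) - (b.shape[0] - 1)
    dx = int(ix) - (b.shape[1] - 1)
    return dx, dy, float(r[iy, ix])


def register_tiles(
    macula: EnFaceImage,
    disc: EnFaceImage,
    min_overlap_frac: float = 0.25,
    min_correlation: float = 0.2,
) -> EnFaceImage:
    """Superimpose the macular and disc tiles into one mosaic.

    Translation-only model (same device, same scale).  The overlap region
    is blended by averaging; fovea and disc landmarks are re-expressed in
    mosaic coordinates.  A correlation below ``min_correlation`` at the
    best shift raises :class:`RegistrationError`.
    """
    if not np.isclose(macula.mm_per_pixel, disc.mm_per_pixel):
        raise ValueError("tiles must share mm_per_pixel")
    dx, dy, corr = estimate_offset(macula, disc, min_overlap_frac)
    if corr < min_correlation:
        raise RegistrationError(
            f"best-shift correlation {corr:.3f} below floor {min_correlation}"
        )
    ha, wa = macula.intensity.shape
    hb, wb = disc.intensity.shape
    y0 = min(0, dy)
    x0 = min(0, dx)
    h = max(ha, dy + hb) - y0
    w = max(wa, dx + wb) - x0
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    vmask = np.zeros((h, w), dtype=bool)

    def paste(img: EnFaceImage, oy: int, ox: int) -> None:
        hh, ww = img.intensity.shape
        acc[oy : oy + hh, ox : ox + ww] += img.intensity
        cnt[oy : oy + hh, ox : ox + ww] += 1
        if img.vessel_mask is not None:
            vmask[oy : oy + hh, ox : ox + ww] |= img.vessel_mask

    paste(macula, -y0, -x0)
    paste(disc, dy - y0, dx - x0)
    mosaic = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    fovea = (macula.fovea_xy[0] - x0, macula.fovea_xy[1] - y0)
    disc_xy = None
    if disc.disc_xy is not None:
        disc_xy = (disc.disc_xy[0] + dx - x0, disc.disc_xy[1] + dy - y0)
    elif macula.disc_xy is not None:
        disc_xy = (macula.disc_xy[0] - x0, macula.disc_xy[1] - y0)
    return EnFaceImage(
        intensity=mosaic,
        mm_per_pixel=macula.mm_per_pixel,
        fovea_xy=fovea,
        disc_xy=disc_xy,
        laterality=macula.laterality,
        vessel_mask=vmask if (macula.vessel_mask is not None or disc.vessel_mask is not None) else None,
    )


def normalize_image(
    img: EnFaceImage,
    gamma: float = 1.0,
    p_low: float = 1.0,
    p_high: float = 99.0,
) -> EnFaceImage:
    """Percentile contrast stretch to [0, 1] followed by gamma correction.

    Monotone and order-preserving.  A constant image cannot be stretched;
    it is returned as all zeros with a logged warning.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    lo, hi = np.percentile(img.intensity, [p_low, p_high])
    if hi <= lo:
        logger.warning("constant image: normalisation returns all zeros")
        out = np.zeros_like(img.intensity, dtype=float)
    else:
        out = np.clip((img.intensity - lo) / (hi - lo), 0.0, 1.0) ** gamma
    return replace(img, intensity=out)
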