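"""Humphrey 10-2 test grid and its projection onto the retinal plane.

The 10-2 perimetry program samples 68 locations on a 2-degree lattice inside
the central 10 degrees of the visual field.  Comparing those locations with
structure seen on an en-face OCT image requires three steps:

1. *Anatomical inversion*: the eye's optics invert the image, so a stimulus
   in the superior visual field lands on the inferior retina and vice versa;
   the horizontal axis mirrors with eye laterality.
2. *Scaling*: visual-field degrees are converted to retinal millimetres.
   The default 0.288 mm/deg is the emmetropic schematic-eye value; no
   axial-length (Littmann) magnification correction is applied, but the
   factor is configurable as a hook for one.
3. *Retinal ganglion cell (RGC) displacement*: within the macula the
   ganglion cell bodies are displaced centrifugally from the cones that
   drive them, so the retinal location that *responds* to a stimulus lies
   radially outward from the location the stimulus lands on.  Each test
   point is therefore pushed outward along its ray from the fovea by a
   smooth unimodal displacement profile.

Coordinate conventions
----------------------
Field coordinates ``(x_deg, y_deg)``: ``x_deg`` positive temporal,
``y_deg`` positive superior.  Retinal coordinates ``(x_mm, y_mm)`` are
fundus-view coordinates with the fovea at the origin, ``x_mm`` increasing
to the viewer's right and ``y_mm`` increasing upward.  For a right eye (OD)
the optic disc sits at positive ``x_mm``; for a left eye (OS) at negative
``x_mm``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

#: Emmetropic schematic-eye conversion factor, mm of retina per degree of
#: visual angle.
MM_PER_DEGREE_DEFAULT = 0.288

#: Squared radius (deg^2) of the lattice cut that reproduces the 68-point
#: 10-2 pattern from the odd-integer lattice.
_RADIUS_SQ_MAX = 82


class Laterality(str, Enum):
    """Eye laterality: OD = right eye, OS = left eye."""

    OD = "OD"
    OS = "OS"


class Hemifield(str, Enum):
    SUPERIOR = "superior"
    INFERIOR = "inferior"


@dataclass(frozen=True)
class FieldPoint:
    """One 10-2 test location in visual-field degrees."""

    index: int
    x_deg: int
    y_deg: int
    cluster: str | None = None

    @property
    def hemifield(self) -> Hemifield:
        return Hemifield.SUPERIOR if self.y_deg > 0 else Hemifield.INFERIOR

    @property
    def eccentricity_deg(self) -> float:
        return float(np.hypot(self.x_deg, self.y_deg))


@dataclass(frozen=True)
class FieldGrid:
    """The ordered 68-point 10-2 grid."""

    points: tuple[FieldPoint, ...]

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[FieldPoint]:
        return iter(self.points)

    def __getitem__(self, i: int) -> FieldPoint:
        return self.points[i]

    def index_of(self, x_deg: int, y_deg: int) -> int:
        """Index of the point at ``(x_deg, y_deg)``; KeyError if absent."""
        for p in self.points:
            if p.x_deg == x_deg and p.y_deg == y_deg:
                return p.index
        raise KeyError(f"no 10-2 point at ({x_deg}, {y_deg})")

    def cluster_indices(self, cluster: str) -> tuple[int, ...]:
        return tuple(p.index for p in self.points if p.cluster == cluster)


@dataclass(frozen=True)
class RetinalPoint:
    """A test point projected onto the retina, relative to the fovea."""

    x_mm: float
    y_mm: float
    displaced: bool
    source_index: int

    @property
    def eccentricity_mm(self) -> float:
        return float(np.hypot(self.x_mm, self.y_mm))


@dataclass(frozen=True)
class MappingConfig:
    """Constants of the field-to-retina projection.

    Parameters
    ----------
    mm_per_degree
        Retinal scale, mm per degree of visual angle.
    peak_deg, peak_amplitude_deg, cutoff_deg
        Parameters of the radial RGC displacement profile: eccentricity of
        maximum displacement, its magnitude (degrees), and the eccentricity
        at and beyond which displacement is zero.  The default profile is a
        smooth unimodal bump (zero at the fovea, peak near 1.8 deg, zero
        beyond 13 deg) matching the qualitative shape of published macular
        displacement curves; an exact literature parameterisation can be
        substituted by changing these three numbers.
    """

    mm_per_degree: float = MM_PER_DEGREE_DEFAULT
    peak_deg: float = 1.8
    peak_amplitude_deg: float = 1.2
    cutoff_deg: float = 13.0

    def __post_init__(self) -> None:
        if self.mm_per_degree <= 0:
            raise ValueError("mm_per_degree must be positive")
        if not (0 < self.peak_deg < self.cutoff_deg):
            raise ValueError("require 0 < peak_deg < cutoff_deg")
        if self.peak_amplitude_deg < 0:
            raise ValueError("peak_amplitude_deg must be >= 0")


def build_grid_10_2() -> FieldGrid:
    """Construct the 68-point 10-2 grid.

    The pattern is the odd-integer-degree lattice in [-9, 9]^2 restricted to
    x^2 + y^2 <= 82, which yields exactly 68 points.  Ordering is row-major
    from the superior row downward, left to right within a row.
    """
    pts: list[FieldPoint] = []
    idx = 0
    for y in range(9, -10, -2):
        for x in range(-9, 10, 2):
            if x * x + y * y <= _RADIUS_SQ_MAX:
                pts.append(FieldPoint(index=idx, x_deg=x, y_deg=y))
                idx += 1
    return FieldGrid(points=tuple(pts))


def default_c1_mask(grid: FieldGrid) -> frozenset[int]:
    """Default papillomacular (C1) cluster membership.

    The papillomacular bundle serves the field strip between fixation and
    the blind spot, i.e. the innermost rows on the temporal side.  The
    default mask is the 12 points with |y| = 1 deg lying at x >= -1 deg:
    the temporal |y| = 1 strip plus the four central points.  It is a
    configuration default, not device metadata, and can be overridden.
    """
    return frozenset(
        p.index for p in grid if abs(p.y_deg) == 1 and p.x_deg >= -1
    )


def assign_clusters(
    grid: FieldGrid, c1_mask: Iterable[int] | None = None
) -> FieldGrid:
    """Label every point C1 / C2 / C3.

    C1 is the papillomacular area given by ``c1_mask`` (default
    :func:`default_c1_mask`); C2 is the superior hemifield excluding C1;
    C3 is the inferior hemifield excluding C1.
    """
    mask = frozenset(default_c1_mask(grid) if c1_mask is None else c1_mask)
    bad = [i for i in mask if not (0 <= i < len(grid))]
    if bad:
        raise ValueError(f"invalid C1 indices: {sorted(bad)}")
    pts = []
    for p in grid:
        if p.index in mask:
            c = "C1"
        elif p.y_deg > 0:
            c = "C2"
        else:
            c = "C3"
        pts.append(replace(p, cluster=c))
    return FieldGrid(points=tuple(pts))


def displacement_deg(
    ecc_deg: float | np.ndarray, cfg: MappingConfig
) -> np.ndarray:
    """Radial RGC displacement (deg) as a function of eccentricity (deg).

    Smooth unimodal bump: zero at the fovea, maximum ``peak_amplitude_deg``
    at ``peak_deg``, identically zero at and beyond ``cutoff_deg``,
    continuous everywhere.
    """
    p, amp, c = cfg.peak_deg, cfg.peak_amplitude_deg, cfg.cutoff_deg
    e = np.asarray(ecc_deg, dtype=float)
    k = (c - p) / p
    out = np.zeros_like(e)
    inside = (e > 0) & (e < c)
    ei = e[inside]
    out[inside] = (ei / p) * ((c - ei) / (c - p)) ** k
    return amp * out


def field_to_retina(
    p: FieldPoint,
    laterality: Laterality | str,
    cfg: MappingConfig | None = None,
) -> RetinalPoint:
    """Project a field point onto the retina (no RGC displacement).

    Superior field maps to inferior retina (y sign flip); the horizontal
    axis mirrors with laterality so that the optic disc always lies on the
    nasal side of the fundus frame.
    """
    cfg = cfg or MappingConfig()
    sign = 1.0 if Laterality(laterality) is Laterality.OD else -1.0
    return RetinalPoint(
        x_mm=sign * p.x_deg * cfg.mm_per_degree,
        y_mm=-p.y_deg * cfg.mm_per_degree,
        displaced=False,
        source_index=p.index,
    )


def retina_to_field_degrees(
    r: RetinalPoint,
    laterality: Laterality | str,
    cfg: MappingConfig | None = None,
) -> tuple[float, float]:
    """Exact inverse of :func:`field_to_retina` (degrees, undisplaced)."""
    cfg = cfg or MappingConfig()
    sign = 1.0 if Laterality(laterality) is Laterality.OD else -1.0
    return (sign * r.x_mm / cfg.mm_per_degree, -r.y_mm / cfg.mm_per_degree)


def apply_rgc_displacement(
    r: RetinalPoint, cfg: MappingConfig | None = None
) -> RetinalPoint:
    """Push a retinal point radially outward by the displacement profile.

    The polar angle about the fovea is preserved exactly; only the
    eccentricity grows, by ``displacement_deg`` evaluated at the point's
    eccentricity in degrees.
    """
    if r.displaced:
        raise ValueError("displacement already applied to this point")
    cfg = cfg or MappingConfig()
    ecc_mm = r.eccentricity_mm
    if ecc_mm == 0.0:
        return replace(r, displaced=True)
    ecc_deg = ecc_mm / cfg.mm_per_degree
    new_ecc_deg = ecc_deg + float(displacement_deg(ecc_deg, cfg))
    scale = new_ecc_deg / ecc_deg
    return RetinalPoint(
        x_mm=r.x_mm * scale,
        y_mm=r.y_mm * scale,
        displaced=True,
        source_index=r.source_index,
    )


def map_grid(
    grid: FieldGrid,
    laterality: Laterality | str,
    cfg: MappingConfig | None = None,
    displace: bool = True,
) -> list[RetinalPoint]:
    """Project the whole grid onto the retina, optionally with displacement."""
    cfg = cfg or MappingConfig()
    out = []
    for p in grid:
        r = field_to_retina(p, laterality, cfg)
        if displace:
            r = apply_rgc_displacement(r, cfg)
        out.append(r)
    return out


def rotate180_index_map(grid: FieldGrid) -> np.ndarray:
    """Index permutation sending each point to its 180-degree rotation.

    This is the permutation realised by physically turning the fundus
    overlay upside down to read it in visual-field orientation.  It is an
    involution by the grid's central symmetry.
    """
    perm = np.empty(len(grid), dtype=int)
    for p in grid:
        perm[p.index] = grid.index_of(-p.x_deg, -p.y_deg)
    return perm


def grid_to_dataframe(
    grid: FieldGrid, mapped: Sequence[RetinalPoint] | None = None
) -> pd.DataFrame:
    """Tabulate the grid (and optionally its retinal projection)."""
    df = pd.DataFrame(
        {
            "index": [p.index for p in grid],
            "x_deg": [p.x_deg for p in grid],
            "y_deg": [p.y_deg for p in grid],
            "hemifield": [p.hemifield.value for p in grid],
            "cluster": [p.cluster for p in grid],
        }
    )
    if mapped is not None:
        by_idx = {r.source_index: r for r in mapped}
        df["x_mm"] = [by_idx[i].x_mm for i in df["index"]]
        df["y_mm"] = [by_idx[i].y_mm for i in df["index"]]
        df["displaced"] = [by_idx[i].displaced for i in df["index"]]
    return df


def export_grid(
    grid: FieldGrid,
    path: str | Path,
    mapped: Sequence[RetinalPoint] | None = None,
) -> None:
    """Write the grid table as CSV or JSON depending on the suffix."""
    path = Path(path)
    df = grid_to_dataframe(grid, mapped)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def load_mapping_config(
    path: str | Path,
) -> tuple[MappingConfig, frozenset[int] | None]:
    """Read a MappingConfig (and optional C1 mask) from a YAML file.

    Recognised keys: ``mm_per_degree``, ``displacement.peak_deg``,
    ``displacement.peak_amplitude_deg``, ``displacement.cutoff_deg``,
    ``c1_mask`` (list of grid indices).
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    disp = data.get("displacement", {}) or {}
    cfg = MappingConfig(
        mm_per_degree=data.get("mm_per_degree", MM_PER_DEGREE_DEFAULT),
        peak_deg=disp.get("peak_deg", 1.8),
        peak_amplitude_deg=disp.get("peak_amplitude_deg", 1.2),
        cutoff_deg=disp.get("cutoff_deg", 13.0),
    )
    mask = data.get("c1_mask")
    return cfg, (frozenset(int(i) for i in mask) if mask is not None else None)
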