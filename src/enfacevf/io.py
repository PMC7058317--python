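"""File formats: en-face images with JSON sidecars, exam tables, overlays.

Images travel as 16-bit grayscale PNG plus a JSON sidecar holding the
physical scale, landmarks and laterality; vessel masks as companion PNGs.
Exams travel as a per-point CSV plus a JSON header of reliability indices
and refraction metadata.  All tabular outputs are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .concordance import ProbCategory, VisualFieldExam
from .enface import EnFaceImage
from .mapping import Laterality, RetinalPoint

_U16 = 65535


def save_enface(img: EnFaceImage, prefix: str | Path) -> None:
    """Write ``{prefix}.png`` (+ vessel mask, + ``{prefix}.json`` sidecar)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scale = float(img.intensity.max()) or 1.0
    raw = np.clip(img.intensity / scale, 0, 1)
    iio.imwrite(prefix.with_suffix(".png"), (raw * _U16).astype(np.uint16))
    if img.vessel_mask is not None:
        iio.imwrite(
            prefix.parent / f"{prefix.name}_vessels.png",
            (img.vessel_mask.astype(np.uint8) * 255),
        )
    sidecar = {
        "mm_per_pixel": img.mm_per_pixel,
        "fovea_xy": list(img.fovea_xy),
        "disc_xy": list(img.disc_xy) if img.disc_xy is not None else None,
        "laterality": Laterality(img.laterality).value,
        "intensity_scale": scale,
        "has_vessel_mask": img.vessel_mask is not None,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_enface(prefix: str | Path) -> EnFaceImage:
    """Read an image written by :func:`save_enface`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    raw = iio.imread(prefix.with_suffix(".png")).astype(float) / _U16
    vessel = None
    if meta.get("has_vessel_mask"):
        vessel = iio.imread(prefix.parent / f"{prefix.name}_vessels.png") > 0
    return EnFaceImage(
        intensity=raw * meta["intensity_scale"],
        mm_per_pixel=meta["mm_per_pixel"],
        fovea_xy=tuple(meta["fovea_xy"]),
        disc_xy=tuple(meta["disc_xy"]) if meta["disc_xy"] else None,
        laterality=meta["laterality"],
        vessel_mask=vessel,
    )


def save_exam(exam: VisualFieldExam, prefix: str | Path) -> None:
    """Write ``{prefix}_points.csv`` and ``{prefix}_meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "index": np.arange(exam.td_db.size),
            "sensitivity": exam.sensitivity_db,
            "td": exam.td_db,
            "pd": exam.pd_db,
            "td_prob": [ProbCategory(int(c)).label for c in exam.td_prob],
            "pd_prob": [ProbCategory(int(c)).label for c in exam.pd_prob],
        }
    )
    df.to_csv(prefix.parent / f"{prefix.name}_points.csv", index=False)
    meta = {
        "fixation_loss_rate": exam.fixation_loss_rate,
        "false_pos_rate": exam.false_pos_rate,
        "false_neg_rate": exam.false_neg_rate,
        "md_10_2": exam.md_10_2,
        "spherical_equivalent": exam.spherical_equivalent,
        "laterality": Laterality(exam.laterality).value,
    }
    (prefix.parent / f"{prefix.name}_meta.json").write_text(
        json.dumps(meta, indent=1)
    )


def load_exam(prefix: str | Path) -> VisualFieldExam:
    """Read an exam written by :func:`save_exam`."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.parent / f"{prefix.name}_points.csv").sort_values(
        "index"
    )
    meta = json.loads((prefix.parent / f"{prefix.name}_meta.json").read_text())
    return VisualFieldExam(
        sensitivity_db=df["sensitivity"].to_numpy(float),
        td_db=df["td"].to_numpy(float),
        pd_db=df["pd"].to_numpy(float),
        td_prob=np.array([int(ProbCategory.from_label(s)) for s in df["td_prob"]]),
        pd_prob=np.array([int(ProbCategory.from_label(s)) for s in df["pd_prob"]]),
        fixation_loss_rate=meta["fixation_loss_rate"],
        false_pos_rate=meta["false_pos_rate"],
        false_neg_rate=meta["false_neg_rate"],
        md_10_2=meta["md_10_2"],
        spherical_equivalent=meta["spherical_equivalent"],
        laterality=meta["laterality"],
    )


def save_judgements(
    presence: Sequence[bool],
    indeterminate: Sequence[int],
    path: str | Path,
) -> None:
    """Per-point presence CSV (index, presence, indeterminate flag)."""
    n = len(presence)
    pd.DataFrame(
        {
            "index": np.arange(n),
            "nfb_present": np.asarray(presence, dtype=bool),
            "indeterminate": [i in set(indeterminate) for i in range(n)],
        }
    ).to_csv(path, index=False)


def render_overlay(
    img: EnFaceImage,
    points: Sequence[RetinalPoint],
    presence: Sequence[bool],
    path: str | Path,
) -> None:
    """Fundus overlay: white circles where NFBs are present, black where absent."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.imshow(img.intensity, cmap="gray", vmin=0, vmax=max(1.0, img.intensity.max()))
    fx, fy = img.fovea_xy
    pres = np.asarray(presence, dtype=bool)
    for pt in points:
        cx = fx + pt.x_mm / img.mm_per_pixel
        cy = fy - pt.y_mm / img.mm_per_pixel
        face = "white" if pres[pt.source_index] else "black"
        ax.add_patch(
            plt.Circle((cx, cy), radius=3, facecolor=face, edgecolor="gray", lw=0.5)
        )
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
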