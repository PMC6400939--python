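"""Disk formats: 16-bit grayscale TIFF frames plus CSV label tables.

A cohort on disk is one directory of ``{biopsy_id}_site{k}.tif`` frames and
a ``cohort.csv`` with one row per site carrying the tissue/subtype/agent
labels, the pathology annotations and the acquisition metadata needed for
calibration.  Intensities are rounded to uint16 on write; at the generator's
intensity scale that quantisation is far below pixel noise.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .imaging import FluorescenceFrame
from .synthetic import Biopsy, SiteAnnotation

COHORT_COLUMNS = [
    "biopsy_id", "site", "tissue_class", "subtype", "agent",
    "pta", "cellularity", "stromal_pct", "til_pct",
    "gain", "exposure", "session_id",
]


def frame_filename(biopsy_id: str, site: int) -> str:
    return f"{biopsy_id}_site{site}.tif"


def write_cohort(biopsies: list[Biopsy], out_dir: str | Path) -> Path:
    """Write frames as 16-bit TIFF and labels/annotations as cohort.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in biopsies:
        for k, (frame, ann) in enumerate(zip(b.frames, b.annotations)):
            data = np.clip(np.round(frame.pixels), 0, 65535).astype(np.uint16)
            tifffile.imwrite(out_dir / frame_filename(b.biopsy_id, k), data)
            rows.append({
                "biopsy_id": b.biopsy_id, "site": k,
                "tissue_class": b.tissue_class, "subtype": b.subtype,
                "agent": b.agent,
                "pta": ann.percent_tumor_area,
                "cellularity": ann.tumor_cellularity,
                "stromal_pct": ann.stromal_percent,
                "til_pct": ann.til_percent_of_stroma,
                "gain": frame.gain, "exposure": frame.exposure,
                "session_id": frame.session_id,
            })
    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    csv_path = out_dir / "cohort.csv"
    table.to_csv(csv_path, index=False)
    return csv_path


def read_cohort(cohort_dir: str | Path) -> list[Biopsy]:
    """Reconstruct Biopsy objects from a cohort directory.

    The circular field-of-view mask is re-derived from the frame shape (the
    mask is a fixed property of the imaging geometry, not of the sample).
    """
    from .synthetic import circular_mask

    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.csv")
    biopsies = []
    for biopsy_id, sub in table.groupby("biopsy_id", sort=False):
        sub = sub.sort_values("site")
        frames, annotations = [], []
        for _, row in sub.iterrows():
            pixels = tifffile.imread(
                cohort_dir / frame_filename(biopsy_id, int(row["site"]))
            ).astype(float)
            frames.append(FluorescenceFrame(
                pixels=pixels, mask=circular_mask(*pixels.shape),
                gain=float(row["gain"]), exposure=float(row["exposure"]),
                session_id=str(row["session_id"]),
            ))
            annotations.append(SiteAnnotation(
                percent_tumor_area=float(row["pta"]),
                tumor_cellularity=float(row["cellularity"]),
                stromal_percent=float(row["stromal_pct"]),
                til_percent_of_stroma=float(row["til_pct"]),
            ))
        first = sub.iloc[0]
        biopsies.append(Biopsy(
            biopsy_id=str(biopsy_id), tissue_class=str(first["tissue_class"]),
            subtype=str(first["subtype"]), frames=frames,
            annotations=annotations, agent=str(first["agent"]),
        ))
    return biopsies


def write_stitched_preview(layout: np.ndarray, path: str | Path) -> None:
    """8-bit PNG preview of a stitched image (display only)."""
    lo, hi = float(layout.min()), float(layout.max())
    scaled = np.zeros_like(layout) if hi <= lo else (layout - lo) / (hi - lo)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)
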