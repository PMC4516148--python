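"""Fibroid characterization and the surgical-planning report.

Individual fibroids are 26-connected components of the fibroid label.
Each is measured (voxel count, volume, maximum diameter as the largest
pairwise distance between voxel centers, centroid) and classified into the
standard anatomical taxonomy:

* **submucosal** — the lesion reaches the endometrial cavity (its one-voxel
  dilation intersects the endometrium);
* **subserosal** — more than a configurable fraction (default 10%) of its
  voxels lie outside the filled uterine-body mask, i.e. it protrudes
  through the serosa;
* **intramural** — otherwise: confined to the myometrial wall.

The rules are evaluated in that priority order.  The removal
recommendation and procedure suggestion are explicit, configurable
heuristics for exercising the planning report end to end — they are NOT
clinical decision rules: submucosal and subserosal fibroids are always
flagged, intramural ones only at or above a diameter threshold; the
procedure follows the type pattern of the removal set (only submucosal →
transcervical resection; any subserosal → laparoscopically assisted
myomectomy; otherwise → total laparoscopic myomectomy).  Abdominal
myomectomy is never auto-suggested.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .volume_io import BODY, ENDOMETRIUM, FIBROID, LabelMap

Procedure = Literal["AM", "LAM", "TLM", "TCR"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FibroidRecord:
    """Measurements and classification of one fibroid component."""

    id: int
    voxel_count: int
    volume_mm3: float
    max_diameter_mm: float
    centroid_mm: tuple[float, float, float]
    kind: str | None = None  # intramural | subserosal | submucosal
    removal_recommended: bool = False
    voxel_indices: np.ndarray | None = None  # (N, 3) int, for classification


@dataclass
class PlanningReport:
    """Per-case counts, per-type breakdown and the suggested procedure."""

    fibroids: list[FibroidRecord]
    total_count: int
    counts_by_type: dict[str, int]
    n_removal_recommended: int
    suggested_procedure: str | None


def find_fibroids(
    labelmap: LabelMap,
    min_voxels: int = 5,
) -> list[FibroidRecord]:
    """One record per 26-connected fibroid component of at least
    ``min_voxels`` voxels, with measurements in mm using the anisotropic
    voxel spacing."""
    spacing = np.asarray(labelmap.spacing)
    voxel_volume = float(np.prod(spacing))
    mask = labelmap.labels == FIBROID
    records: list[FibroidRecord] = []
    if not mask.any():
        return records
    comp, n = ndimage.label(mask, structure=_CONN26)
    next_id = 1
    for c in range(1, n + 1):
        idx = np.argwhere(comp == c)
        if len(idx) < min_voxels:
            continue
        centers = idx * spacing + np.asarray(labelmap.origin)
        records.append(
            FibroidRecord(
                id=next_id,
                voxel_count=len(idx),
                volume_mm3=len(idx) * voxel_volume,
                max_diameter_mm=max_pairwise_distance(centers),
                centroid_mm=tuple(float(x) for x in centers.mean(axis=0)),
                voxel_indices=idx,
            )
        )
        next_id += 1
    return records


def max_pairwise_distance(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance in a point set (its diameter).

    The diameter of a finite set equals the diameter of its convex hull
    vertices, so the all-pairs search runs on the hull (with a direct
    all-pairs fallback for small or degenerate sets).
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 1:
        return 0.0
    if len(points) > 50:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # coplanar/collinear sets: brute force below
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max())


def classify_fibroid(
    record: FibroidRecord,
    body_mask: np.ndarray,
    endometrium_mask: np.ndarray,
    spacing: Sequence[float] | None = None,
    subserosal_fraction: float = 0.10,
) -> str:
    """Classify one fibroid as submucosal, subserosal or intramural.

    ``body_mask`` is the body label (holes carved by nested structures are
    filled internally before the exterior-fraction test).
    """
    if record.voxel_indices is None or len(record.voxel_indices) == 0:
        raise ValueError("record has no voxels to classify")
    shape = body_mask.shape
    fmask = np.zeros(shape, dtype=bool)
    fmask[tuple(record.voxel_indices.T)] = True

    dilated = ndimage.binary_dilation(fmask, structure=_CONN26)
    if (dilated & endometrium_mask).any():
        return "submucosal"

    # exterior test against the filled body label: an intramural lesion
    # carves a hole in label 1 (filled back here); a subserosal protrusion
    # is a surface bite, which filling does not close
    outside = fmask & ~ndimage.binary_fill_holes(body_mask)
    fraction_outside = outside.sum() / fmask.sum()
    if fraction_outside > subserosal_fraction:
        return "subserosal"
    return "intramural"


def classify_all(
    records: list[FibroidRecord],
    labelmap: LabelMap,
    subserosal_fraction: float = 0.10,
) -> list[FibroidRecord]:
    """Classify every record in place against the label map's body and
    endometrium masks."""
    body = labelmap.labels == BODY
    endo = labelmap.labels == ENDOMETRIUM
    for r in records:
        r.kind = classify_fibroid(r, body, endo, labelmap.spacing, subserosal_fraction)
    return records


def build_report(
    records: list[FibroidRecord],
    intramural_removal_diameter_mm: float = 25.0,
) -> PlanningReport:
    """Assemble the planning report from classified records.

    Removal is recommended for every submucosal and subserosal fibroid and
    for intramural fibroids with maximum diameter at or above the
    threshold.  The suggested procedure follows the type pattern of the
    removal set; with no removals no procedure is suggested.
    """
    if any(r.kind is None for r in records):
        raise ValueError("records must be classified before building a report")
    counts = {"intramural": 0, "subserosal": 0, "submucosal": 0}
    for r in records:
        counts[r.kind] += 1
        r.removal_recommended = (
            r.kind in ("submucosal", "subserosal")
            or r.max_diameter_mm >= intramural_removal_diameter_mm
        )
    removals = [r for r in records if r.removal_recommended]
    procedure: str | None
    if not removals:
        procedure = None
    elif all(r.kind == "submucosal" for r in removals):
        procedure = "TCR"
    elif any(r.kind == "subserosal" for r in removals):
        procedure = "LAM"
    else:
        procedure = "TLM"
    return PlanningReport(
        fibroids=records,
        total_count=len(records),
        counts_by_type=counts,
        n_removal_recommended=len(removals),
        suggested_procedure=procedure,
    )


def report_to_frame(report: PlanningReport) -> pd.DataFrame:
    """Per-fibroid table of the report (one row per lesion)."""
    rows = [
        {
            "id": r.id,
            "voxel_count": r.voxel_count,
            "volume_mm3": round(r.volume_mm3, 2),
            "max_diameter_mm": round(r.max_diameter_mm, 2),
            "centroid_x_mm": round(r.centroid_mm[0], 2),
            "centroid_y_mm": round(r.centroid_mm[1], 2),
            "centroid_z_mm": round(r.centroid_mm[2], 2),
            "type": r.kind,
            "removal_recommended": r.removal_recommended,
        }
        for r in report.fibroids
    ]
    return pd.DataFrame(rows)


def save_report(report: PlanningReport, path: str | os.PathLike) -> None:
    """Write the report as CSV (per-fibroid rows) or JSON (full structure)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "total_count": report.total_count,
            "counts_by_type": report.counts_by_type,
            "n_removal_recommended": report.n_removal_recommended,
            "suggested_procedure": report.suggested_procedure,
            "fibroids": report_to_frame(report).to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        report_to_frame(report).to_csv(path, index=False)
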