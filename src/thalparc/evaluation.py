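"""Agreement metrics between two parcellations of one subject.

Four per-nucleus metrics quantify how well an atlas-based segmentation
matches the direct cluster-based one:

* Dice overlap ``2|A∩B| / (|A∩B| + |A∪B|)`` — identical to the classical
  ``2|A∩B| / (|A| + |B|)`` by inclusion–exclusion;
* percentage volume difference ``(V_atlas − V_clust) / V_clust × 100``;
* Euclidean distance between nucleus centroids (mm);
* maximum distance from centroid to any nucleus voxel (mm) — a radius-like
  scale against which the centroid distance can be judged.

Summaries report per-nucleus mean ± sd (n−1 denominator) plus median and
quartiles, one row per nucleus and hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

import numpy as np
import pandas as pd

from .io import ColorLUT
from .types import LabeledVolume

METRICS = (
    "dice",
    "pct_vol_diff",
    "centroid_distance_mm",
    "max_radius_atlas_mm",
    "max_radius_clust_mm",
)


@dataclass
class EvaluationRecord:
    nucleus_code: int
    nucleus_name: str
    hemisphere: str
    dice: float
    pct_vol_diff: float
    centroid_distance_mm: float
    max_radius_atlas_mm: float
    max_radius_clust_mm: float
    missing: bool = False


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two voxel sets given as boolean grids."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("voxel sets must share one grid")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("Dice of two empty sets is 0 by convention", stacklevel=2)
        return 0.0
    return 2.0 * inter / (inter + union)


def pct_volume_difference(v_atlas: float, v_clust: float) -> float:
    """Signed volume mismatch in percent, relative to the cluster volume."""
    if v_clust <= 0:
        raise ValueError("reference (cluster) volume must be positive")
    return (v_atlas - v_clust) / v_clust * 100.0


def centroid(volume: LabeledVolume, code: int) -> np.ndarray:
    """World-mm centroid: mean of voxel-center coordinates with ``code``."""
    voxels = volume.voxels_of(code)
    if len(voxels) == 0:
        raise KeyError(f"label code {code} absent from volume")
    return volume.world_coords(voxels).mean(axis=0)


def centroid_distance(c1: np.ndarray, c2: np.ndarray) -> float:
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("points must have equal dimensionality")
    return float(np.linalg.norm(c1 - c2))


def max_radius(volume: LabeledVolume, code: int) -> float:
    """Largest centroid-to-voxel distance of a nucleus (mm)."""
    voxels = volume.voxels_of(code)
    if len(voxels) == 0:
        raise KeyError(f"label code {code} absent from volume")
    coords = volume.world_coords(voxels)
    return float(np.linalg.norm(coords - coords.mean(axis=0), axis=1).max())


def _hemisphere(name: str) -> str:
    if name.startswith(("L-", "Left-", "lh-")):
        return "left"
    if name.startswith(("R-", "Right-", "rh-")):
        return "right"
    return "unknown"


def evaluate_pair(
    p_atlas: LabeledVolume,
    p_clust: LabeledVolume,
    lut: ColorLUT | None = None,
) -> list[EvaluationRecord]:
    """All four metrics for every nucleus code shared by both parcellations.

    Codes present in only one parcellation yield a record with
    ``missing=True`` and NaN metrics rather than being dropped silently.
    """
    if p_atlas.labels.shape != p_clust.labels.shape:
        raise ValueError("parcellations must share one grid")
    names = lut.names if lut is not None else {**p_clust.label_table, **p_atlas.label_table}
    codes_a = set(p_atlas.codes)
    codes_c = set(p_clust.codes)
    shared = sorted(codes_a & codes_c)
    if not shared:
        raise ValueError("parcellations share no label codes")
    records = []
    for code in sorted(codes_a | codes_c):
        name = names.get(code, f"label{code}")
        hemi = _hemisphere(name)
        if code not in shared:
            records.append(
                EvaluationRecord(code, name, hemi, math.nan, math.nan, math.nan, math.nan, math.nan, missing=True)
            )
            continue
        in_a = p_atlas.labels == code
        in_c = p_clust.labels == code
        records.append(
            EvaluationRecord(
                nucleus_code=code,
                nucleus_name=name,
                hemisphere=hemi,
                dice=dice(in_a, in_c),
                pct_vol_diff=pct_volume_difference(np.count_nonzero(in_a), np.count_nonzero(in_c)),
                centroid_distance_mm=centroid_distance(centroid(p_atlas, code), centroid(p_clust, code)),
                max_radius_atlas_mm=max_radius(p_atlas, code),
                max_radius_clust_mm=max_radius(p_clust, code),
            )
        )
    return records


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def summarize(records: list[EvaluationRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-nucleus summary across subjects: mean, sd, median, quartiles.

    Only records where both parcellations contained the nucleus contribute;
    single-observation groups report sd 0 and carry ``n = 1``.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to summarize")
    frame = frame[~frame["missing"].astype(bool)]
    if frame.empty:
        raise ValueError("all records are missing-flagged")
    rows = []
    for (code, name, hemi), grp in frame.groupby(["nucleus_code", "nucleus_name", "hemisphere"], sort=True):
        row: dict = {"nucleus_code": code, "nucleus_name": name, "hemisphere": hemi, "n": len(grp)}
        for metric in METRICS:
            vals = grp[metric].to_numpy(dtype=float)
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row[f"{metric}_median"] = float(np.median(vals))
            row[f"{metric}_q25"] = float(np.percentile(vals, 25))
            row[f"{metric}_q75"] = float(np.percentile(vals, 75))
        rows.append(row)
    return pd.DataFrame(rows)
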