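"""Segmentation evaluation metrics: Dice, HD95 and normalized surface distance.

Surface voxels are foreground voxels with at least one background 6-neighbour
(the volume border counts as background).  Directed surface distances from
every surface voxel of one mask to the nearest surface voxel of the other are
pooled over both directions; HD95 is the 95th percentile of that pooled set
(linear interpolation) and the NSD is the fraction of pooled distances within
a tolerance (default 1 mm — the convention this package uses; absolute NSD
values depend on it).  Distances are in millimetres via the voxel spacing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

#: sentinel for metrics on an empty mask, excluded from aggregation
EMPTY_SENTINEL = float("nan")


def dice_coeff(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap 2|A n B| / (|A| + |B|); two empty masks count as identical."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of foreground voxels with a background 6-neighbour."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(mask.ndim, 1),
        border_value=0)
    return mask & ~eroded


def _pooled_surface_distances(a, b, spacing):
    sa = surface_voxels(a)
    sb = surface_voxels(b)
    if not sa.any() or not sb.any():
        return None
    spacing = np.asarray(spacing, dtype=float)
    # EDT of the complement of a surface gives, at every voxel, the distance
    # to that surface; sample it at the other mask's surface voxels.
    dist_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dist_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return np.concatenate([dist_to_b[sa], dist_to_a[sb]])


def hd95(a: np.ndarray, b: np.ndarray,
         spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled symmetric surface distances (mm)."""
    d = _pooled_surface_distances(a, b, spacing)
    if d is None:
        return EMPTY_SENTINEL
    return float(np.percentile(d, 95))


def nsd(a: np.ndarray, b: np.ndarray, tolerance_mm: float = 1.0,
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Fraction of pooled surface distances within ``tolerance_mm``."""
    if tolerance_mm <= 0:
        raise ValueError("tolerance_mm must be > 0")
    d = _pooled_surface_distances(a, b, spacing)
    if d is None:
        return EMPTY_SENTINEL
    return float((d <= tolerance_mm).mean())


def _position_group(code: str) -> str:
    return {"C": "cervical", "T": "thoracic", "L": "lumbar"}.get(code[:1], "other")


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Per-vertebra rows plus per-position and overall aggregate rows.

    Each input row needs subject_id, vertebra_label, dice, hd95, nsd.
    Aggregates report mean and quartiles per metric; NaN (empty-mask
    sentinel) rows are excluded from aggregation.
    """
    table = pd.DataFrame(rows)
    table["position"] = table["vertebra_label"].map(_position_group)
    aggs = []
    groups = [("overall", table)] + [
        (name, g) for name, g in table.groupby("position", sort=True)]
    for name, g in groups:
        entry = dict(subject_id="<aggregate>", vertebra_label=name,
                     position=name, n=len(g))
        for metric in ("dice", "hd95", "nsd"):
            vals = g[metric].dropna()
            entry[metric] = vals.mean() if len(vals) else np.nan
            entry[f"{metric}_q1"] = vals.quantile(0.25) if len(vals) else np.nan
            entry[f"{metric}_q3"] = vals.quantile(0.75) if len(vals) else np.nan
        aggs.append(entry)
    return pd.concat([table, pd.DataFrame(aggs)], ignore_index=True)
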