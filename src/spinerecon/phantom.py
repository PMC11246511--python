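"""Synthetic spine phantoms.

Stands in for labelled CT: each vertebra is an elliptic-cylinder "body" with a
posterior bar (spinous process) and two lateral bars (transverse processes),
stacked along the axial axis with a configurable gap into a spine volume with
per-vertebra integer labels, anatomical position codes and voxel centroids.
Intensity is two-level (bone vs background) plus additive Gaussian noise
clipped to be nonnegative.

Axis convention: axis 0 = sagittal (left-right), axis 1 = coronal
(anterior-posterior), axis 2 = axial (inferior-superior).  The posterior
direction is +axis 1.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

#: anatomical position codes in inferior-to-superior order of stacking use;
#: includes the T13/L6 anatomical variants seen in population imaging.
POSITION_CODES = ([f"C{i}" for i in range(1, 8)]
                  + [f"T{i}" for i in range(1, 14)]
                  + [f"L{i}" for i in range(1, 7)])

#: VerSe-style integer codes for annotation files (1-7 C1-C7, 8-19 T1-T12,
#: 20-25 L1-L6, 28 = T13).
CODE_TO_INT = {f"C{i}": i for i in range(1, 8)}
CODE_TO_INT.update({f"T{i}": 7 + i for i in range(1, 13)})
CODE_TO_INT.update({f"L{i}": 19 + i for i in range(1, 7)})
CODE_TO_INT["T13"] = 28
INT_TO_CODE = {v: k for k, v in CODE_TO_INT.items()}


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the synthetic spine.

    Ranges are half-open ``(low, high)`` intervals in voxels, sampled per
    vertebra.  Defaults are the desk-scale preset: a 64 x 64 x 96 volume with
    3-5 vertebrae, small enough that every downstream stage runs in seconds.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 96)
    n_vertebrae: int = 4
    body_radius_range: tuple[float, float] = (6.0, 9.0)
    body_height_range: tuple[float, float] = (10.0, 14.0)
    process_length_range: tuple[float, float] = (6.0, 10.0)
    gap: int = 4
    intensity_bone: float = 1000.0
    intensity_background: float = 50.0
    noise_sd: float = 20.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    start_code: str = "T10"
    seed: int = 0

    def __post_init__(self):
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if self.intensity_bone <= self.intensity_background:
            raise ValueError("intensity_bone must exceed intensity_background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("body_radius_range", "body_height_range",
                     "process_length_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a nonempty nonnegative interval")
        if self.start_code not in POSITION_CODES:
            raise ValueError(f"unknown start_code {self.start_code!r}")


@dataclasses.dataclass
class SpineRecord:
    """One subject: intensity volume, label volume, centroid table, spacing."""

    intensity: np.ndarray
    labels: np.ndarray
    centroids: pd.DataFrame          # columns: vertebra_label, label_id, x, y, z
    spacing: tuple[float, float, float]
    subject_id: str

    def __post_init__(self):
        if self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and labels must share shape")
        for _, row in self.centroids.iterrows():
            x, y, z = int(row.x), int(row.y), int(row.z)
            if self.labels[x, y, z] != row.label_id:
                raise ValueError(
                    f"centroid of {row.vertebra_label} at {(x, y, z)} does not "
                    f"lie inside its labelled component")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape


def _ellipse_mask(shape, center, rx, ry, half_h):
    x, y, z = np.ogrid[:shape[0], :shape[1], :shape[2]]
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    return ((dx / rx) ** 2 + (dy / ry) ** 2 <= 1.0) & (np.abs(dz) <= half_h)


def make_vertebra_phantom(spec: PhantomSpec, center: tuple[int, int, int],
                          rng: np.random.Generator | None = None):
    """One vertebra mask on the full volume grid.

    Returns ``(mask, centroid)`` where the centroid is the rounded voxel mean
    of the elliptic-cylinder body.  The body radii/height and process lengths
    are drawn from the spec's ranges with ``rng`` (or from ``spec.seed``).
    """
    rng = rng or np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    rx = rng.uniform(*spec.body_radius_range)
    ry = rng.uniform(*spec.body_radius_range)
    h = rng.uniform(*spec.body_height_range)
    plen = rng.uniform(*spec.process_length_range)
    margin = max(rx, ry)
    for ax in range(2):
        if not (margin <= center[ax] <= shape[ax] - 1 - margin):
            raise ValueError(
                f"vertebra center {center} is within {margin:.1f} voxels of the "
                f"volume boundary on axis {ax} (shape {shape})")
    if not (h / 2 <= center[2] <= shape[2] - 1 - h / 2):
        raise ValueError(
            f"vertebra center {center} too close to the axial boundary for "
            f"height {h:.1f} (shape {shape})")

    body = _ellipse_mask(shape, center, rx, ry, h / 2)
    mask = body.copy()
    x, y, z = np.ogrid[:shape[0], :shape[1], :shape[2]]
    bar_r = max(1, int(round(min(rx, ry) / 3)))
    if plen >= 1.0:
        # posterior spinous process: bar along +axis1 starting inside the body
        y1 = min(shape[1], int(round(center[1] + ry + plen)))
        spin = ((np.abs(x - center[0]) <= bar_r) & (y >= center[1]) & (y < y1)
                & (np.abs(z - center[2]) <= bar_r))
        # two lateral transverse processes along +/- axis0
        tlen = plen * 0.7
        x0 = max(0, int(round(center[0] - rx - tlen)))
        x1 = min(shape[0], int(round(center[0] + rx + tlen)))
        trans = ((np.abs(y - center[1]) <= bar_r) & (x >= x0) & (x < x1)
                 & (np.abs(z - center[2]) <= bar_r))
        mask |= spin | trans
    centroid = tuple(int(round(c)) for c in np.argwhere(body).mean(axis=0))
    return mask, centroid


def make_spine_phantom(spec: PhantomSpec) -> SpineRecord:
    """Stack ``n_vertebrae`` phantom vertebrae into one labelled spine volume."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    start = POSITION_CODES.index(spec.start_code)
    if start + spec.n_vertebrae > len(POSITION_CODES):
        raise ValueError("not enough position codes from start_code")
    codes = POSITION_CODES[start:start + spec.n_vertebrae]

    hmax = spec.body_height_range[1]
    need = spec.n_vertebrae * (hmax + spec.gap)
    if need > shape[2]:
        raise ValueError(
            f"{spec.n_vertebrae} vertebrae of height <= {hmax} with gap "
            f"{spec.gap} need {need:.0f} axial voxels; volume has {shape[2]}")

    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    cx, cy = shape[0] // 2, shape[1] // 2 - shape[1] // 8  # room for processes
    z = 0.0
    pitch = shape[2] / spec.n_vertebrae
    for k, code in enumerate(codes, start=1):
        cz = int(round(z + pitch / 2))
        mask, centroid = make_vertebra_phantom(spec, (cx, cy, cz), rng)
        if (labels[mask] != 0).any():
            raise ValueError(f"vertebra {code} overlaps a previous vertebra")
        labels[mask] = k
        rows.append(dict(vertebra_label=code, label_id=k,
                         x=centroid[0], y=centroid[1], z=centroid[2]))
        z += pitch
    centroids = pd.DataFrame(rows)

    bone = labels > 0
    intensity = np.full(shape, spec.intensity_background, dtype=np.float64)
    intensity[bone] = spec.intensity_bone
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, size=shape)
        np.clip(intensity, 0.0, None, out=intensity)
    return SpineRecord(intensity=intensity, labels=labels, centroids=centroids,
                       spacing=spec.spacing, subject_id=f"phantom{spec.seed:04d}")


# ---------------------------------------------------------------------------
# persistence (NIfTI volumes + VerSe-dialect centroid annotation file)


def write_record(record: SpineRecord, directory) -> dict[str, Path]:
    """Write ``<id>_ct.nii.gz``, ``<id>_seg.nii.gz`` and ``<id>_ctd.json``."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(record.spacing) + [1.0])
    paths = {
        "ct": directory / f"{record.subject_id}_ct.nii.gz",
        "seg": directory / f"{record.subject_id}_seg.nii.gz",
        "ctd": directory / f"{record.subject_id}_ctd.json",
    }
    nib.save(nib.Nifti1Image(record.intensity.astype(np.float32), affine),
             paths["ct"])
    nib.save(nib.Nifti1Image(record.labels.astype(np.int16), affine),
             paths["seg"])
    entries = [{"label": int(CODE_TO_INT[row.vertebra_label]),
                "X": float(row.x), "Y": float(row.y), "Z": float(row.z)}
               for _, row in record.centroids.iterrows()]
    paths["ctd"].write_text(json.dumps(entries, indent=1))
    return paths
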