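"""Digitally reconstructed radiographs (DRRs) and vertebra-level patch pairs.

Projection is an orthographic parallel-beam line integral: the coronal view
sums the volume along the anterior-posterior axis (axis 1) and keeps axes
(sagittal, axial); the sagittal view sums along the left-right axis (axis 0)
and keeps (coronal, axial).  Per-patch intensities are min-max normalised to
[0, 1].  Each vertebra yields one PatchPair: an S x S crop of each view
centred on the projected centroid, a binary disk centroid mask per view, and
(when supervised) the S^3 binary target window of that vertebra's label mask.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .phantom import SpineRecord

logger = logging.getLogger(__name__)

#: axes of the volume retained by each view (row axis, column axis)
VIEW_AXES = {"coronal": (0, 2), "sagittal": (1, 2)}
#: the axis integrated over
VIEW_SUM_AXIS = {"coronal": 1, "sagittal": 0}

DEFAULT_PATCH_SIZE = 120
DEFAULT_MASK_RADIUS = 4


@dataclasses.dataclass
class ProjectionImage:
    """A 2D parallel-beam projection plus the mapping back to volume axes."""

    pixels: np.ndarray
    view: str
    spacing: tuple[float, float]
    #: 2x2 affine scale (here identity) mapping pixel indices to the two
    #: retained volume axes; kept explicit so crops can be traced back.
    origin_map: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(2))

    def volume_to_pixel(self, voxel: tuple[float, float, float]) -> tuple[int, int]:
        a, b = VIEW_AXES[self.view]
        inv = np.linalg.inv(self.origin_map)
        r, c = inv @ np.array([voxel[a], voxel[b]], dtype=float)
        return int(round(r)), int(round(c))


@dataclasses.dataclass
class PatchPair:
    """One vertebra's sample: two views, two centroid masks, optional target."""

    coronal_patch: np.ndarray
    sagittal_patch: np.ndarray
    coronal_centroid_mask: np.ndarray
    sagittal_centroid_mask: np.ndarray
    vertebra_label: str
    subject_id: str
    target: np.ndarray | None = None
    #: voxel offset of the target window in the source volume (for assembly)
    crop_offset: tuple[int, int, int] | None = None

    def __post_init__(self):
        s = self.coronal_patch.shape
        arrays = (self.coronal_patch, self.sagittal_patch,
                  self.coronal_centroid_mask, self.sagittal_centroid_mask)
        if any(a.shape != s for a in arrays) or len(s) != 2 or s[0] != s[1]:
            raise ValueError("all four 2D arrays must be square and share size")
        for patch in (self.coronal_patch, self.sagittal_patch):
            if patch.min() < 0 or patch.max() > 1:
                raise ValueError("patch intensities must lie in [0, 1]")
        for mask in (self.coronal_centroid_mask, self.sagittal_centroid_mask):
            if mask.sum() < 1:
                raise ValueError("centroid mask must have >= 1 foreground pixel")
        if self.target is not None and self.target.sum() < 1:
            raise ValueError("target must have >= 1 foreground voxel")

    @property
    def size(self) -> int:
        return self.coronal_patch.shape[0]


def project(volume: np.ndarray, view: str) -> ProjectionImage:
    """Parallel-beam line integral of ``volume`` along the view's ray axis."""
    if view not in VIEW_AXES:
        raise ValueError(f"view must be 'coronal' or 'sagittal', got {view!r}")
    volume = np.asarray(volume)
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite voxels")
    if (volume < 0).any():
        raise ValueError("volume contains negative voxels")
    pixels = volume.sum(axis=VIEW_SUM_AXIS[view], dtype=np.float64)
    return ProjectionImage(pixels=pixels, view=view, spacing=(1.0, 1.0))


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def crop_patch(image: ProjectionImage | np.ndarray, center: tuple[int, int],
               size: int = DEFAULT_PATCH_SIZE) -> np.ndarray:
    """``size x size`` window centred on ``center``; zero-filled off-image.

    For even ``size`` the centre pixel occupies index ``size // 2``
    (half-open convention), i.e. rows ``center[0] - size//2 ..
    center[0] + (size - 1)//2`` inclusive.
    """
    pixels = image.pixels if isinstance(image, ProjectionImage) else np.asarray(image)
    r, c = int(center[0]), int(center[1])
    h, w = pixels.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"center {center} outside image of shape {pixels.shape}")
    lo_r, lo_c = r - size // 2, c - size // 2
    out = np.zeros((size, size), dtype=pixels.dtype)
    src_r = slice(max(lo_r, 0), min(lo_r + size, h))
    src_c = slice(max(lo_c, 0), min(lo_c + size, w))
    dst_r = slice(src_r.start - lo_r, src_r.stop - lo_r)
    dst_c = slice(src_c.start - lo_c, src_c.stop - lo_c)
    out[dst_r, dst_c] = pixels[src_r, src_c]
    return out


def centroid_mask(size: int, center: tuple[int, int],
                  radius: int = DEFAULT_MASK_RADIUS) -> np.ndarray:
    """Binary disk of ``radius`` pixels on a ``size x size`` canvas."""
    r, c = int(center[0]), int(center[1])
    if not (0 <= r < size and 0 <= c < size):
        raise ValueError(f"center {center} outside {size} x {size} canvas")
    rows, cols = np.ogrid[:size, :size]
    return ((rows - r) ** 2 + (cols - c) ** 2 <= radius ** 2)


def _crop3d(volume: np.ndarray, center: tuple[int, int, int], size: int):
    """Axis-aligned ``size**3`` window; returns (window, offset)."""
    lo = [int(c) - size // 2 for c in center]
    out = np.zeros((size,) * 3, dtype=volume.dtype)
    src = tuple(slice(max(l, 0), min(l + size, n))
                for l, n in zip(lo, volume.shape))
    dst = tuple(slice(s.start - l, s.stop - l) for s, l in zip(src, lo))
    out[dst] = volume[src]
    return out, tuple(lo)


def build_pairs(record: SpineRecord, size: int = DEFAULT_PATCH_SIZE,
                radius: int = DEFAULT_MASK_RADIUS,
                with_target: bool = True) -> list[PatchPair]:
    """One PatchPair per centroid row of ``record``.

    Both views are projected once, min-max normalised per patch, and cropped
    around the projected 3D centroid; the target is the ``size**3`` window of
    the *annotated* vertebra's binary mask (never a union with neighbours).
    """
    projections = {view: project(record.intensity, view)
                   for view in ("coronal", "sagittal")}
    pairs = []
    for _, row in record.centroids.iterrows():
        voxel = (float(row.x), float(row.y), float(row.z))
        label_id = int(row.label_id)
        vert_mask = record.labels == label_id
        if with_target and not vert_mask.any():
            logger.warning("vertebra %s of %s has an empty label mask; skipped",
                           row.vertebra_label, record.subject_id)
            continue
        patches, masks = {}, {}
        for view, proj in projections.items():
            pr, pc = proj.volume_to_pixel(voxel)
            patches[view] = normalize_image(crop_patch(proj, (pr, pc), size))
            # the projected centroid sits at the crop centre by construction
            masks[view] = centroid_mask(size, (size // 2, size // 2), radius)
        target, offset = (None, None)
        if with_target:
            target, offset = _crop3d(vert_mask, tuple(map(int, voxel)), size)
        pairs.append(PatchPair(
            coronal_patch=patches["coronal"],
            sagittal_patch=patches["sagittal"],
            coronal_centroid_mask=masks["coronal"],
            sagittal_centroid_mask=masks["sagittal"],
            vertebra_label=str(row.vertebra_label),
            subject_id=record.subject_id,
            target=target,
            crop_offset=offset))
    return pairs


def save_patch_png(patch: np.ndarray, path) -> None:
    """Export a [0, 1] patch as an 8-bit PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.clip(patch, 0, 1) * 255).astype(np.uint8))
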