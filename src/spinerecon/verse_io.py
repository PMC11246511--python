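"""VerSe-style case ingestion, resampling, cohort filtering and splitting.

A case is a CT volume, a per-vertebra integer label volume (NIfTI) and a
centroid annotation file (a JSON list of entries with an integer vertebra
label and X/Y/Z voxel coordinates).  The small-cohort filter excludes whole
spines that (a) contain a T13, L6 or any cervical vertebra, (b) have no more
than 2 thoracic vertebrae, or (c) show metal occlusion (an input flag from a
sidecar file; not detected from images).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import INT_TO_CODE, SpineRecord

CERVICAL = {f"C{i}" for i in range(1, 8)}
THORACIC = {f"T{i}" for i in range(1, 14)}
LUMBAR = {f"L{i}" for i in range(1, 7)}
SACRAL = {"S1", "S2"}
KNOWN_CODES = CERVICAL | THORACIC | LUMBAR | SACRAL

RULE_CERVICAL_OR_VARIANT = "cervical_or_T13_L6"
RULE_TOO_FEW_THORACIC = "too_few_thoracic"
RULE_METAL = "metal"


@dataclasses.dataclass
class CaseMeta:
    subject_id: str
    vertebra_codes: frozenset[str]
    has_metal: bool = False

    def __post_init__(self):
        self.vertebra_codes = frozenset(self.vertebra_codes)
        unknown = self.vertebra_codes - KNOWN_CODES
        if unknown:
            raise ValueError(f"unknown vertebra codes: {sorted(unknown)}")


@dataclasses.dataclass
class FilterReport:
    kept: list[str]
    excluded: list[tuple[str, str]]
    n_spines_kept: int
    n_vertebrae_kept: int

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(subject_id=s, status="kept", rule="") for s in self.kept]
        rows += [dict(subject_id=s, status="excluded", rule=r)
                 for s, r in self.excluded]
        return pd.DataFrame(rows)


def exclusion_rule(case: CaseMeta) -> str | None:
    """First matching exclusion rule, or None if the case is kept."""
    codes = case.vertebra_codes
    if "T13" in codes or "L6" in codes or codes & CERVICAL:
        return RULE_CERVICAL_OR_VARIANT
    if len(codes & THORACIC) <= 2:
        return RULE_TOO_FEW_THORACIC
    if case.has_metal:
        return RULE_METAL
    return None


def apply_small_filters(cases: list[CaseMeta]) -> FilterReport:
    """Apply the three whole-spine exclusion rules, in order."""
    kept, excluded = [], []
    n_vert = 0
    for case in cases:
        rule = exclusion_rule(case)
        if rule is None:
            kept.append(case.subject_id)
            n_vert += len(case.vertebra_codes)
        else:
            excluded.append((case.subject_id, rule))
    return FilterReport(kept=kept, excluded=excluded,
                        n_spines_kept=len(kept), n_vertebrae_kept=n_vert)


def read_case(ct_path, seg_path, centroid_path, subject_id: str | None = None
              ) -> SpineRecord:
    """Load a case from NIfTI volumes plus a centroid annotation file."""
    import nibabel as nib

    ct = nib.load(str(ct_path))
    seg = nib.load(str(seg_path))
    intensity = np.asarray(ct.dataobj, dtype=np.float64)
    labels = np.asarray(seg.dataobj, dtype=np.int32)
    if intensity.shape != labels.shape:
        raise ValueError(
            f"grid mismatch: CT {intensity.shape} vs segmentation {labels.shape}")
    spacing = tuple(float(z) for z in ct.header.get_zooms()[:3])

    entries = json.loads(Path(centroid_path).read_text())
    rows = []
    for e in entries:
        if not isinstance(e, dict) or "label" not in e:
            continue  # VerSe files may carry a direction entry; skip non-centroids
        code_int = int(e["label"])
        if code_int not in INT_TO_CODE:
            raise ValueError(f"unknown vertebra label code {code_int}")
        x, y, z = float(e["X"]), float(e["Y"]), float(e["Z"])
        if not (0 <= x < intensity.shape[0] and 0 <= y < intensity.shape[1]
                and 0 <= z < intensity.shape[2]):
            raise ValueError(
                f"centroid {e} lies outside volume {intensity.shape}")
        xi, yi, zi = int(round(x)), int(round(y)), int(round(z))
        # the voxel value at the centroid links the annotation to the label
        # volume (identical to the code in genuine VerSe, sequential ids in
        # the phantom dialect)
        rows.append(dict(vertebra_label=INT_TO_CODE[code_int],
                         label_id=int(labels[xi, yi, zi]),
                         x=xi, y=yi, z=zi))
    centroids = pd.DataFrame(rows)
    return SpineRecord(intensity=intensity, labels=labels, centroids=centroids,
                       spacing=spacing,
                       subject_id=subject_id or Path(ct_path).name.split("_")[0])


def resample_iso(record: SpineRecord, spacing_mm: float = 1.0) -> SpineRecord:
    """Resample to isotropic spacing: trilinear intensity, nearest labels."""
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be positive")
    factors = tuple(s / spacing_mm for s in record.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return record
    intensity = ndimage.zoom(record.intensity, factors, order=1)
    labels = ndimage.zoom(record.labels, factors, order=0)
    # crop/pad nearest-neighbour output onto the intensity grid (zoom may
    # disagree by one voxel on some axes)
    if labels.shape != intensity.shape:
        fixed = np.zeros(intensity.shape, dtype=labels.dtype)
        sl = tuple(slice(0, min(a, b)) for a, b in zip(intensity.shape, labels.shape))
        fixed[sl] = labels[sl]
        labels = fixed
    centroids = record.centroids.copy()
    for ax, col in enumerate(("x", "y", "z")):
        centroids[col] = np.minimum(
            np.round(centroids[col] * factors[ax]).astype(int),
            intensity.shape[ax] - 1)
    return SpineRecord(intensity=intensity, labels=labels, centroids=centroids,
                       spacing=(spacing_mm,) * 3, subject_id=record.subject_id)


def split_by_patient(subject_ids: list[str], ratio: float = 0.8,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Shuffled patient-level split; every record of a patient lands on one
    side.  ``ratio`` is the train fraction (4:1 -> 0.8)."""
    patients = sorted(set(subject_ids))
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    n_train = int(round(len(patients) * ratio))
    n_train = min(max(n_train, 1), len(patients) - 1)
    return sorted(order[:n_train]), sorted(order[n_train:])
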