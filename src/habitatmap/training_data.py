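"""Labeled training data: class-annotated ROIs plus the synthetic novelty class.

The five-class tissue taxonomy for soft-tissue sarcoma habitats:

    1  enhancing cellular tumor      (low ADC, enhancing)        red
    2  non-enhancing cellular tumor  (low ADC, non-enhancing)    green
    3  necrotic / cystic             (high ADC)                  blue
    4  fat                           (high fat fraction)         yellow
    5  novelty                       (unlike any training class) gray

Classes 1-4 come from small square ROIs (1-2 cm^2, 45-100 voxels) drawn far
from tissue boundaries. Class 5 is synthesized: feature triples sampled
uniformly over the intrinsic parameter ranges so that voxels resembling no
annotated tissue are flagged rather than forced into a tissue class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import parameter_maps as pm
from .parameter_maps import FeatureField
from .volumes_io import MaskVolume

__all__ = [
    "HabitatClass",
    "HABITAT_CLASSES",
    "NOVELTY_CLASS_ID",
    "LabeledROI",
    "TrainingSet",
    "extract_roi_samples",
    "synthesize_novelty_rois",
    "assemble_training_set",
    "load_roi_table",
    "save_training_set",
    "load_training_set",
]

ROI_VOXELS_MIN = 45
ROI_VOXELS_MAX = 100
DEFAULT_NOVELTY_ROIS = 15
NOVELTY_CLASS_ID = 5


@dataclass(frozen=True)
class HabitatClass:
    id: int
    name: str
    color: str


HABITAT_CLASSES: dict[int, HabitatClass] = {
    1: HabitatClass(1, "enhancing cellular tumor", "red"),
    2: HabitatClass(2, "non-enhancing cellular tumor", "green"),
    3: HabitatClass(3, "necrotic/cystic", "blue"),
    4: HabitatClass(4, "fat", "yellow"),
    5: HabitatClass(5, "novelty", "gray"),
}

TISSUE_CLASS_IDS = (1, 2, 3, 4)
ALL_CLASS_IDS = (1, 2, 3, 4, 5)


@dataclass
class LabeledROI:
    """Feature samples of one ROI carrying one class label."""

    roi_id: str
    patient_id: str
    class_id: int
    samples: np.ndarray  # (n, 3) normalized (adc_n, ef_n, ff_n)
    timepoint: str = "pre"

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != 3:
            raise ValueError("ROI samples must be (n, 3) feature rows")
        if self.class_id not in ALL_CLASS_IDS:
            raise ValueError(f"class_id must be in {ALL_CLASS_IDS}, got {self.class_id}")
        if self.samples.min() < 0 or self.samples.max() > 1:
            raise ValueError(f"ROI {self.roi_id}: samples outside the unit cube")
        if self.class_id in TISSUE_CLASS_IDS and not (
            ROI_VOXELS_MIN <= self.voxel_count <= ROI_VOXELS_MAX
        ):
            warnings.warn(
                f"ROI {self.roi_id}: {self.voxel_count} voxels is outside the "
                f"expected image-ROI size range [{ROI_VOXELS_MIN}, {ROI_VOXELS_MAX}]",
                stacklevel=2,
            )

    @property
    def voxel_count(self) -> int:
        return self.samples.shape[0]


@dataclass
class TrainingSet:
    """A collection of labeled ROIs with pooled-matrix accessors."""

    rois: list = field(default_factory=list)

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for roi in self.rois:
            counts[roi.class_id] = counts.get(roi.class_id, 0) + 1
        return counts

    def rois_by_class(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for roi in self.rois:
            out.setdefault(roi.class_id, []).append(roi)
        return out

    def matrices(self, exclude_roi_ids=()) -> tuple[np.ndarray, np.ndarray]:
        """Pooled ``(X, y)`` over all ROIs not in ``exclude_roi_ids``."""
        excl = set(exclude_roi_ids)
        xs, ys = [], []
        for roi in self.rois:
            if roi.roi_id in excl:
                continue
            xs.append(roi.samples)
            ys.append(np.full(roi.voxel_count, roi.class_id, dtype=int))
        if not xs:
            raise ValueError("training set selection is empty")
        return np.vstack(xs), np.concatenate(ys)

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def n_samples(self) -> int:
        return sum(r.voxel_count for r in self.rois)


def extract_roi_samples(features: FeatureField, roi_mask: MaskVolume, class_id: int,
                        roi_id: str = "", patient_id: str = "",
                        timepoint: str = "pre") -> LabeledROI:
    """Collect one feature row per valid voxel under a training-ROI mask."""
    if class_id not in TISSUE_CLASS_IDS:
        raise ValueError(f"image ROIs carry tissue classes {TISSUE_CLASS_IDS}, "
                         f"got {class_id}")
    if roi_mask.size == 0:
        raise ValueError(f"ROI mask {roi_mask.label!r} is empty")
    X, _ = features.samples(roi_mask)
    if X.shape[0] == 0:
        raise ValueError(
            f"ROI {roi_mask.label!r} has no valid voxels in the feature field"
        )
    return LabeledROI(roi_id=roi_id or roi_mask.label, patient_id=patient_id,
                      class_id=class_id, samples=X, timepoint=timepoint)


def synthesize_novelty_rois(n_rois: int = DEFAULT_NOVELTY_ROIS,
                            voxels_per_roi=None,
                            seed: int | np.random.Generator = 0) -> list:
    """Synthesize class-5 ROIs by uniform sampling of the parameter ranges.

    Parameters are drawn uniformly over their intrinsic ranges -- EF in
    [-100, 100] %, FF in [0, 100] %, ADC in [0, 3e-3] mm^2/s -- and passed
    through the standard normalization, so every normalized component is
    Uniform(0, 1). ROI sizes default to uniform integers in [45, 100],
    mirroring the image-ROI size range.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rois = []
    for i in range(n_rois):
        n = (int(voxels_per_roi(rng)) if callable(voxels_per_roi)
             else int(voxels_per_roi) if voxels_per_roi is not None
             else int(rng.integers(ROI_VOXELS_MIN, ROI_VOXELS_MAX + 1)))
        adc = rng.uniform(0.0, pm.ADC_MAX, n)
        ef = rng.uniform(*pm.EF_RANGE, n)
        ff = rng.uniform(*pm.FF_RANGE, n)
        samples = np.stack(
            [pm.normalize_adc(adc), pm.normalize_ef(ef), pm.normalize_ff(ff)], axis=1
        )
        rois.append(LabeledROI(roi_id=f"novelty-{i:02d}", patient_id="synthetic",
                               class_id=NOVELTY_CLASS_ID, samples=samples))
    return rois


def assemble_training_set(image_rois, novelty_rois=(),
                          holdout_patients=()) -> tuple[TrainingSet, TrainingSet]:
    """Split image ROIs into a cross-validation set and a held-out test set.

    Hold-out is by patient: every ROI of a held-out patient moves to the test
    set. Synthetic novelty ROIs always stay in the cross-validation set. A
    tissue class left with zero cross-validation ROIs is a hard error, since
    a five-class model can no longer be fitted.
    """
    holdout = set(holdout_patients)
    known = {r.patient_id for r in image_rois}
    unknown = holdout - known
    if unknown:
        raise ValueError(f"unknown holdout patient ids: {sorted(unknown)}")
    cv_rois = [r for r in image_rois if r.patient_id not in holdout]
    test_rois = [r for r in image_rois if r.patient_id in holdout]
    cv_set = TrainingSet(rois=cv_rois + list(novelty_rois))
    counts = cv_set.class_counts()
    present_tissue = {r.class_id for r in image_rois}
    missing = [c for c in sorted(present_tissue) if counts.get(c, 0) == 0]
    if missing:
        raise ValueError(
            f"classes {missing} have no ROIs left after holding out {sorted(holdout)}"
        )
    return cv_set, TrainingSet(rois=test_rois)


def load_roi_table(path) -> pd.DataFrame:
    """Read the ROI sidecar CSV (roi_id, patient_id, timepoint, class_id, mask_path)."""
    table = pd.read_csv(path, dtype={"roi_id": str, "patient_id": str})
    required = {"roi_id", "patient_id", "class_id", "mask_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ROI table is missing columns: {sorted(missing)}")
    if "timepoint" not in table.columns:
        table["timepoint"] = "pre"
    return table


def save_training_set(training: TrainingSet, path) -> Path:
    """Serialize as one CSV row per voxel sample."""
    rows = []
    for roi in training.rois:
        for x in roi.samples:
            rows.append((roi.roi_id, roi.patient_id, roi.timepoint, roi.class_id,
                         x[0], x[1], x[2]))
    frame = pd.DataFrame(
        rows, columns=["roi_id", "patient_id", "timepoint", "class_id",
                       "adc_n", "ef_n", "ff_n"]
    )
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def load_training_set(path) -> TrainingSet:
    frame = pd.read_csv(path, dtype={"roi_id": str, "patient_id": str})
    rois = []
    for (roi_id, patient_id, timepoint, class_id), grp in frame.groupby(
        ["roi_id", "patient_id", "timepoint", "class_id"], sort=False
    ):
        rois.append(LabeledROI(roi_id=str(roi_id), patient_id=str(patient_id),
                               class_id=int(class_id),
                               samples=grp[["adc_n", "ef_n", "ff_n"]].to_numpy(),
                               timepoint=str(timepoint)))
    return TrainingSet(rois=rois)
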