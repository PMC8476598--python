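"""Stage 3: confidence filtering, curation and the refined biomarker model.

A *digital biomarker* is a tumor region the stage-2 model associates with
one outcome group at high confidence. This module

1. thresholds the stage-2 confidence maps per class and keeps only
   contiguous foci of at least a minimum physical size (default 200 µm
   equivalent circular diameter, 8-connected components);
2. emulates the curation review by subtracting exclusion classes
   (necrosis, stroma, artifact, blur) and re-applying the size filter,
   since subtraction can fragment a focus below the minimum size;
3. retrains a final 200 µm-field-of-view segmentation model on the curated
   biomarker annotations, in replicate: same data and training parameters,
   different seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .learners import PatchLearner, TrainParams, dense_feature_maps, features_at
from .slide_core import ClassMask, FieldOfView, SlideImage, grid_centers
from .stage2_weak_outcome import ConfidenceMap

__all__ = [
    "DigitalBiomarkerMask",
    "RefinedModel",
    "curate_annotations",
    "filter_high_confidence",
    "min_focus_area_px",
    "remove_small_foci",
    "train_refined_model",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)
MIN_FOCUS_UM_DEFAULT = 200.0


@dataclass(frozen=True)
class DigitalBiomarkerMask:
    """A per-slide biomarker mask with the provenance of its extraction."""

    slide_id: str
    class_name: str  # "dbm_short" | "dbm_long"
    mask: np.ndarray
    confidence_threshold: float
    min_focus_um: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def as_class_mask(self) -> ClassMask:
        return ClassMask(self.slide_id, self.class_name, self.mask)


def min_focus_area_px(min_focus_um: float, resolution_um_per_px: float) -> float:
    """Pixel area of a disc whose equivalent circular diameter equals
    ``min_focus_um``: components strictly smaller than this are discarded.

    Equivalent circular diameter of a component with area A px is
    2·sqrt(A/π)·resolution (rotation-invariant, unambiguous).
    """
    radius_px = min_focus_um / (2.0 * resolution_um_per_px)
    return np.pi * radius_px * radius_px


def remove_small_foci(
    mask: np.ndarray, min_focus_um: float, resolution_um_per_px: float
) -> np.ndarray:
    """Drop 8-connected components with equivalent diameter < min_focus_um."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    lab, nlab = ndimage.label(mask, structure=EIGHT_CONN)
    if nlab == 0:
        return mask.copy()
    min_area = min_focus_area_px(min_focus_um, resolution_um_per_px)
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, nlab + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(lab, keep)


def filter_high_confidence(
    conf: ConfidenceMap,
    threshold: float,
    min_focus_um: float,
    resolution_um_per_px: float,
) -> tuple[DigitalBiomarkerMask, DigitalBiomarkerMask]:
    """Extract the (short, long) digital-biomarker mask pair.

    Per class: pixels with confidence >= threshold, then the minimum-focus
    size filter. A threshold above 0.5 makes the two masks disjoint by the
    confidence normalization. Idempotent on its own output.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"confidence threshold must be in (0.5, 1], got {threshold}")
    if min_focus_um <= 0:
        raise ValueError(f"min_focus_um must be positive, got {min_focus_um}")
    out = []
    for cls, arr in (("dbm_short", conf.conf_short), ("dbm_long", conf.conf_long)):
        raw = np.nan_to_num(arr, nan=0.0) >= threshold
        filt = remove_small_foci(raw & conf.tumor_mask, min_focus_um, resolution_um_per_px)
        out.append(
            DigitalBiomarkerMask(conf.slide_id, cls, filt, threshold, min_focus_um)
        )
    return out[0], out[1]


def curate_annotations(
    dbm_masks: Sequence[DigitalBiomarkerMask],
    exclusion_masks: Sequence[np.ndarray],
    resolution_um_per_px: float,
) -> list[DigitalBiomarkerMask]:
    """Subtract exclusion classes and re-apply the minimum-focus filter.

    The exclusion masks stand in for the review step that removes necrosis,
    stroma, tissue artifact and blur from the biomarker annotations.
    """
    excl = None
    for m in exclusion_masks:
        excl = np.asarray(m, dtype=bool) if excl is None else (excl | np.asarray(m, bool))
    curated = []
    for dbm in dbm_masks:
        m = dbm.mask if excl is None else (dbm.mask & ~excl)
        m = remove_small_foci(m, dbm.min_focus_um, resolution_um_per_px)
        curated.append(
            DigitalBiomarkerMask(
                dbm.slide_id, dbm.class_name, m, dbm.confidence_threshold, dbm.min_focus_um
            )
        )
    return curated


@dataclass
class RefinedModel:
    """A replicate of the final biomarker segmentation model (200 µm FOV)."""

    learner: PatchLearner
    fov: FieldOfView
    replicate_id: int
    seed: int
    call_threshold: float = 0.75

    def confidence_maps(self, slide: SlideImage, stride_px: int = 1) -> dict[str, np.ndarray]:
        conf = self.learner.confidence_maps(slide.pixels, self.fov.patch_px, stride_px)
        return {
            "dbm_short": conf[..., self.learner.classes_.index("dbm_short")],
            "dbm_long": conf[..., self.learner.classes_.index("dbm_long")],
        }


def train_refined_model(
    slides: Sequence[SlideImage],
    curated: Mapping[str, Sequence[DigitalBiomarkerMask]],
    params: TrainParams | None = None,
    seeds: Sequence[int] = (0, 1),
    fov_um: float = 200.0,
    stride_px: int | None = None,
    call_threshold: float = 0.75,
) -> list[RefinedModel]:
    """Train the final model in replicate on curated biomarker annotations.

    ``curated`` maps slide_id to its (short, long) biomarker masks. All
    replicates share data and training parameters and differ only in seed.
    Raises, naming the class, if a biomarker class is empty cohort-wide.
    """
    params = params or TrainParams()
    fov = FieldOfView(fov_um, slides[0].resolution_um_per_px)
    stride = stride_px or max(1, fov.patch_px // 2)
    X, y = [], []
    for slide in slides:
        masks = curated.get(slide.slide_id)
        if not masks:
            continue
        maps = None
        for dbm in masks:
            if not dbm.mask.any():
                continue
            centers = grid_centers(slide.shape, stride)
            keep = dbm.mask[centers[:, 0], centers[:, 1]]
            centers = centers[keep]
            if centers.size == 0:
                continue
            if maps is None:
                maps = dense_feature_maps(slide.pixels, fov.patch_px)
            X.append(features_at(maps, centers))
            y.extend([dbm.class_name] * len(centers))
    for cls in ("dbm_short", "dbm_long"):
        if cls not in y:
            raise ValueError(
                f"biomarker class {cls!r} is empty across the training cohort; "
                "cannot train the refined model"
            )
    Xc, yc = np.concatenate(X), np.asarray(y)
    models = []
    for rep, seed in enumerate(seeds, start=1):
        learner = PatchLearner(params=params).fit_features(Xc, yc, seed=seed)
        models.append(
            RefinedModel(
                learner=learner,
                fov=fov,
                replicate_id=rep,
                seed=seed,
                call_threshold=call_threshold,
            )
        )
    return models
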