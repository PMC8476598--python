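"""Stage 2: weakly supervised outcome association (the workflow's core).

Tumor regions found by stage 1 are *relabeled with the outcome group of the
patient* — not of the pixel — and a patch classifier is trained at a 500 µm
field of view to associate tumor texture with PFI_S vs PFI_L. Label noise on
outcome-discordant regions is accepted by design; the signal that survives
is precisely what the confidence filter of stage 3 extracts.

Evaluation of this stage is only meaningful patient-disjoint (weak labels
leak trivially between patches of the same patient).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .learners import PatchLearner, TrainParams, dense_feature_maps, features_at
from .slide_core import (
    ClassMask,
    FieldOfView,
    MetadataError,
    Outcome,
    SlideImage,
    grid_centers,
)

__all__ = [
    "ConfidenceMap",
    "WeakTrainingSet",
    "build_weak_set",
    "infer_confidence",
    "train_outcome_model",
]

OUTCOME_FOV_UM = 500.0


@dataclass
class WeakTrainingSet:
    """Patch features with patient-level weak labels and full provenance."""

    X: np.ndarray
    y: np.ndarray  # outcome group value per patch ("PFI_S"/"PFI_L")
    provenance: pd.DataFrame  # slide_id, patient_id, row, col
    fov: FieldOfView

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class ConfidenceMap:
    """Per-pixel outcome confidences, defined only inside the tumor mask.

    ``conf_short`` and ``conf_long`` are NaN outside the tumor mask and sum
    to 1 wherever defined. ``empty`` flags a slide whose stage-1 mask had no
    tumor at all.
    """

    slide_id: str
    conf_short: np.ndarray
    conf_long: np.ndarray
    tumor_mask: np.ndarray

    @property
    def empty(self) -> bool:
        return not bool(self.tumor_mask.any())


def build_weak_set(
    slides: Sequence[SlideImage],
    tumor_masks: Sequence[ClassMask],
    outcome_by_patient: Mapping[str, Outcome],
    fov_um: float = OUTCOME_FOV_UM,
    stride_px: int | None = None,
    seed: int = 0,
    balance: bool = True,
) -> WeakTrainingSet:
    """Sample grid patches inside tumor masks and weak-label them.

    Classes are balanced by subsampling the majority class (the cohorts this
    emulates are near-balanced, so this removes a nuisance without discarding
    much data). Patient provenance is retained per patch so evaluation can
    hold out whole patients.
    """
    fov = FieldOfView(fov_um, slides[0].resolution_um_per_px)
    stride = stride_px or max(1, fov.patch_px // 2)
    feats, labels, prov = [], [], []
    for slide, mask in zip(slides, tumor_masks):
        mask.require_congruent(slide)
        if slide.patient_id not in outcome_by_patient:
            raise MetadataError(
                f"slide {slide.slide_id}: patient {slide.patient_id!r} has no outcome label"
            )
        group = outcome_by_patient[slide.patient_id]
        centers = grid_centers(slide.shape, stride)
        keep = mask.mask[centers[:, 0], centers[:, 1]]
        centers = centers[keep]
        if centers.size == 0:
            continue
        maps = dense_feature_maps(slide.pixels, fov.patch_px)
        feats.append(features_at(maps, centers))
        labels.extend([group.value] * len(centers))
        prov.extend(
            {
                "slide_id": slide.slide_id,
                "patient_id": slide.patient_id,
                "row": int(r),
                "col": int(c),
            }
            for r, c in centers
        )
    if not feats:
        X = np.empty((0, 0))
        y = np.array([], dtype=object)
        return WeakTrainingSet(X, y, pd.DataFrame(prov), fov)
    X = np.concatenate(feats)
    y = np.asarray(labels)
    df = pd.DataFrame(prov)
    if balance and len(np.unique(y)) == 2:
        rng = np.random.default_rng(seed)
        idx_by = {c: np.flatnonzero(y == c) for c in np.unique(y)}
        n_min = min(len(v) for v in idx_by.values())
        keep_idx = np.sort(
            np.concatenate(
                [
                    v if len(v) == n_min else rng.choice(v, size=n_min, replace=False)
                    for v in idx_by.values()
                ]
            )
        )
        X, y, df = X[keep_idx], y[keep_idx], df.iloc[keep_idx].reset_index(drop=True)
    return WeakTrainingSet(X, y, df, fov)


def train_outcome_model(
    weak_set: WeakTrainingSet,
    params: TrainParams | None = None,
    seed: int = 0,
) -> PatchLearner:
    """Fit the outcome-association model on the weak training set."""
    params = params or TrainParams()
    return PatchLearner(params=params).fit_features(weak_set.X, weak_set.y, seed=seed)


def infer_confidence(
    model: PatchLearner,
    slide: SlideImage,
    tumor_mask: ClassMask,
    fov_um: float = OUTCOME_FOV_UM,
    stride_px: int = 1,
) -> ConfidenceMap:
    """Dense outcome-confidence rasters inside the tumor mask.

    An empty tumor mask yields an all-NaN (flagged) map rather than an error.
    """
    tumor_mask.require_congruent(slide)
    fov = FieldOfView(fov_um, slide.resolution_um_per_px)
    tm = tumor_mask.mask
    if not tm.any():
        nanmap = np.full(slide.shape, np.nan)
        return ConfidenceMap(slide.slide_id, nanmap, nanmap.copy(), tm)
    conf = model.confidence_maps(slide.pixels, fov.patch_px, stride_px)
    i_short = model.classes_.index(Outcome.PFI_S.value)
    i_long = model.classes_.index(Outcome.PFI_L.value)
    conf_short = np.where(tm, conf[..., i_short], np.nan)
    conf_long = np.where(tm, conf[..., i_long], np.nan)
    return ConfidenceMap(slide.slide_id, conf_short, conf_long, tm)
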