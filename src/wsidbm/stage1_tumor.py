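"""Stage 1: supervised tumor segmentation (the workflow's first network).

A patch classifier is trained at a 200 µm field of view to separate tumor
from everything that must not enter the analysis — background, stroma,
artifacts, whitespace and extensive necrosis. Pixel-level tumor annotations
(here: the generator's ground-truth masks, standing in for a pathologist's
manual annotation) provide the hard labels.

Inference thresholds the per-pixel tumor confidence; the default inference
stride of 1 gives true per-pixel output, larger strides rasterize patch
predictions by nearest-center assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .learners import PatchLearner, TrainParams, dense_feature_maps, features_at
from .slide_core import ClassMask, FieldOfView, SlideImage, grid_centers

__all__ = ["TumorSegmenter", "train_tumor_segmenter", "segment_tumor"]

TUMOR_FOV_UM = 200.0


@dataclass
class TumorSegmenter:
    learner: PatchLearner
    fov: FieldOfView
    train_stride_px: int
    infer_stride_px: int = 1
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")

    def tumor_confidence(self, slide: SlideImage) -> np.ndarray:
        conf = self.learner.confidence_maps(
            slide.pixels, self.fov.patch_px, self.infer_stride_px
        )
        return conf[..., self.learner.classes_.index("tumor")]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "learner": self.learner.to_dict(),
                    "fov_um": self.fov.fov_um,
                    "resolution_um_per_px": self.fov.resolution_um_per_px,
                    "train_stride_px": self.train_stride_px,
                    "infer_stride_px": self.infer_stride_px,
                    "threshold": self.threshold,
                    "seed": self.seed,
                }
            )
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TumorSegmenter":
        d = json.loads(Path(path).read_text())
        return cls(
            learner=PatchLearner.from_dict(d["learner"]),
            fov=FieldOfView(d["fov_um"], d["resolution_um_per_px"]),
            train_stride_px=d["train_stride_px"],
            infer_stride_px=d["infer_stride_px"],
            threshold=d["threshold"],
            seed=d["seed"],
        )


def train_tumor_segmenter(
    slides: Sequence[SlideImage],
    tumor_masks: Sequence[ClassMask],
    params: TrainParams | None = None,
    seed: int = 0,
    fov_um: float = TUMOR_FOV_UM,
    stride_px: int | None = None,
    threshold: float = 0.5,
    infer_stride_px: int = 1,
) -> TumorSegmenter:
    """Fit the tumor-vs-rest segmenter from annotated slides.

    Training examples are grid patch centers (stride defaults to half the
    field of view); the label of a center is "tumor" iff it falls inside the
    slide's tumor annotation. Raises if the annotations contain one class
    only.
    """
    if len(slides) < 2:
        raise ValueError("need at least two annotated slides")
    params = params or TrainParams()
    fov = FieldOfView(fov_um, slides[0].resolution_um_per_px)
    stride = stride_px or max(1, fov.patch_px // 2)
    X, y = [], []
    for slide, mask in zip(slides, tumor_masks):
        mask.require_congruent(slide)
        maps = dense_feature_maps(slide.pixels, fov.patch_px)
        centers = grid_centers(slide.shape, stride)
        X.append(features_at(maps, centers))
        lab = np.where(mask.mask[centers[:, 0], centers[:, 1]], "tumor", "rest")
        y.append(lab)
    learner = PatchLearner(params=params).fit_features(
        np.concatenate(X), np.concatenate(y), seed=seed
    )
    return TumorSegmenter(
        learner=learner,
        fov=fov,
        train_stride_px=stride,
        infer_stride_px=infer_stride_px,
        threshold=threshold,
        seed=seed,
    )


def segment_tumor(seg: TumorSegmenter, slide: SlideImage) -> ClassMask:
    """Binary tumor mask at slide resolution.

    Thresholding the tumor confidence at 0 degenerates to a full-frame mask;
    a tumor-free slide yields a (near-)empty mask. Raising the threshold can
    only shrink the mask.
    """
    conf = seg.tumor_confidence(slide)
    return ClassMask(slide.slide_id, "tumor", conf >= seg.threshold)
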