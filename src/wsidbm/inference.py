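"""Combined inference pipeline and the area-ratio outcome classifier.

The tumor segmenter (stage 1) and the refined biomarker model (stage 3) are
not integrated at the model level: the biomarker model is simply masked by
the tumor segmentation. Per slide, the percent of tumor area called for
each biomarker class is measured, their short/long ratio is computed from
unrounded percentages, and slides are classified by a single ratio cutoff
(default 30, the value the original workflow found to fit its validation
set; ratio ≥ cutoff predicts the short-PFI group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .slide_core import ClassMask, Outcome, SlideImage
from .stage1_tumor import TumorSegmenter, segment_tumor
from .stage3_refinement import RefinedModel

__all__ = [
    "CutoffRule",
    "RatioUndefinedError",
    "SlideScore",
    "classify_slides",
    "compute_ratio",
    "display_ratio",
    "run_inference",
]

#: Half of one displayed decimal of a percentage: a long-biomarker area that
#: prints as 0.0 % is still treated as positive ("does not represent true
#: 0 %"), keeping every ratio finite without dividing by zero.
RATIO_EPSILON = 0.005


class RatioUndefinedError(ZeroDivisionError):
    """Both biomarker areas are exactly zero; the ratio carries no signal."""


@dataclass(frozen=True)
class SlideScore:
    """Per-slide biomarker areas (% of tumor area) and classification."""

    slide_id: str
    long_dbm_pct: float
    short_dbm_pct: float
    ratio: float | None = None
    prediction: Outcome | None = None
    replicate_id: int | None = None
    flagged: bool = False
    unclassified_pct: float | None = None

    def __post_init__(self) -> None:
        if not self.flagged and self.long_dbm_pct + self.short_dbm_pct > 100.0 + 1e-9:
            raise ValueError(
                f"{self.slide_id}: biomarker areas exceed the tumor area "
                f"({self.short_dbm_pct} + {self.long_dbm_pct} > 100)"
            )


@dataclass(frozen=True)
class CutoffRule:
    """ratio >= cutoff → PFI_S; one threshold per replicate, no per-slide
    exceptions. The ≥ convention is fixed by the printed validation results
    (a ratio displaying 30.2 is called short, 25.7 long; exactly 30.0 never
    occurs, so the boundary is a convention)."""

    cutoff: float = 30.0

    def predict(self, ratio: float) -> Outcome:
        return Outcome.PFI_S if ratio >= self.cutoff else Outcome.PFI_L


def compute_ratio(
    short_pct: float, long_pct: float, epsilon: float = RATIO_EPSILON
) -> float:
    """Short/long biomarker area ratio from *unrounded* percentages.

    ``epsilon`` (default half of one displayed decimal) floors the
    denominator so a long area that merely displays as 0.0 % still yields a
    finite ratio. Raises :class:`RatioUndefinedError` when both areas are
    exactly zero.
    """
    if short_pct < 0 or long_pct < 0:
        raise ValueError("percentages must be non-negative")
    if short_pct == 0.0 and long_pct == 0.0:
        raise RatioUndefinedError("both biomarker areas are zero")
    return short_pct / max(long_pct, epsilon)


def display_ratio(ratio: float) -> float:
    """Ratio as displayed: one decimal, half-up."""
    import decimal

    return float(
        decimal.Decimal(repr(ratio)).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


def run_inference(
    nn1: TumorSegmenter,
    nn3: RefinedModel,
    slide: SlideImage,
) -> SlideScore:
    """Score one slide with the combined pipeline (no classification yet).

    Biomarker calls are made only inside the stage-1 tumor mask and the
    tumor area is the denominator. Pixels confident for neither class count
    as unclassified, so short% + long% + unclassified% = 100. A slide whose
    tumor mask comes back empty is returned flagged (excluded from ranking
    downstream) with a warning.
    """
    tumor = segment_tumor(nn1, slide)
    if tumor.area_px == 0:
        warnings.warn(
            f"slide {slide.slide_id}: empty tumor segmentation; score flagged",
            stacklevel=2,
        )
        return SlideScore(
            slide.slide_id,
            long_dbm_pct=float("nan"),
            short_dbm_pct=float("nan"),
            replicate_id=nn3.replicate_id,
            flagged=True,
        )
    conf = nn3.confidence_maps(slide)
    t = nn3.call_threshold
    short_mask = (conf["dbm_short"] >= t) & tumor.mask
    long_mask = (conf["dbm_long"] >= t) & tumor.mask
    denom = tumor.area_px
    short_pct = 100.0 * short_mask.sum() / denom
    long_pct = 100.0 * long_mask.sum() / denom
    return SlideScore(
        slide.slide_id,
        long_dbm_pct=float(long_pct),
        short_dbm_pct=float(short_pct),
        replicate_id=nn3.replicate_id,
        unclassified_pct=float(100.0 - short_pct - long_pct),
    )


def biomarker_masks(
    nn1: TumorSegmenter, nn3: RefinedModel, slide: SlideImage
) -> dict[str, ClassMask]:
    """The pipeline's biomarker segmentation masks (inside the tumor mask)."""
    tumor = segment_tumor(nn1, slide)
    conf = nn3.confidence_maps(slide)
    t = nn3.call_threshold
    return {
        "tumor": tumor,
        "dbm_short": ClassMask(slide.slide_id, "dbm_short", (conf["dbm_short"] >= t) & tumor.mask),
        "dbm_long": ClassMask(slide.slide_id, "dbm_long", (conf["dbm_long"] >= t) & tumor.mask),
    }


def classify_slides(
    scores: Sequence[SlideScore],
    rule: CutoffRule = CutoffRule(),
    epsilon: float = RATIO_EPSILON,
) -> list[SlideScore]:
    """Rank slides by their short/long ratio and apply the cutoff rule.

    Returns new scores sorted ascending by ratio (ties broken by slide id
    for determinism) with ``ratio`` and ``prediction`` filled in. Flagged
    scores are excluded. The rank order itself is presentational — the
    prediction depends only on (ratio, cutoff) — so permuting the input
    permutes nothing but the output order.
    """
    out = []
    for s in scores:
        if s.flagged:
            continue
        ratio = s.ratio if s.ratio is not None else compute_ratio(
            s.short_dbm_pct, s.long_dbm_pct, epsilon
        )
        out.append(replace(s, ratio=ratio, prediction=rule.predict(ratio)))
    return sorted(out, key=lambda s: (s.ratio, s.slide_id))
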