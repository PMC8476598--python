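"""Synthetic virtual-slide cohorts with per-pixel ground truth.

The generator emulates the statistical structure the outcome-classification
workflow assumes, without any imaging data dependency:

* two patient groups at the extremes of platinum response (PFI_S / PFI_L),
  by default 17 vs 13 patients with 2–13 slides each, mirroring the cohort
  shape the workflow was designed for (at much smaller slide rasters);
* heterogeneous intra-tumor texture mixtures: each tumor is a spatial mosaic
  of a "short-like" texture, a "long-like" texture and a neutral filler, with
  the outcome-concordant texture over-represented by ``mixture_bias``;
* excludable nuisance classes — necrosis, stroma, folded tissue, blur,
  whitespace — that a curation step must remove.

Textures are procedural (band-limited Gaussian noise with class-specific
chromatic profile and spatial frequency), not photorealistic H&E; they are
separable by simple patch statistics with overlap controlled by ``contrast``
(``contrast = 0`` collapses short-like and long-like onto one distribution,
the negative-control condition).

Generation is a pure function of the spec (which carries the seed): the RNG
stream of each slide is derived from the slide's position in the cohort, so
regenerating, reordering work, or renaming patient ids never changes pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .slide_core import (
    ClassMask,
    MetadataError,
    Outcome,
    OutcomeLabel,
    SlideImage,
    read_cohort_table,
    read_mask,
    read_slide,
    write_cohort_table,
    write_slide,
)

__all__ = [
    "ARTIFACT_NOMINAL_FRACTION",
    "NECROSIS_LUMINANCE_MARGIN",
    "TEXTURE_PALETTE",
    "CohortData",
    "CohortSpec",
    "GroundTruth",
    "generate_cohort",
    "inject_artifacts",
    "load_cohort",
    "make_validation_spec",
    "render_texture",
    "texture_params",
    "write_cohort",
]


@dataclass(frozen=True)
class TextureParams:
    base_rgb: tuple[float, float, float]
    amp_rgb: tuple[float, float, float]
    sigma_fine: float
    sigma_coarse: float
    w_coarse: float


# Chromatic profiles are loosely H&E-evocative: tumor textures sit in the
# eosin/hematoxylin gamut, stroma is pale pink, necrosis is dark and dull.
# The names "papillary_like"/"solid_like" are evocative labels only.
TEXTURE_PALETTE: Mapping[str, TextureParams] = {
    "short_like": TextureParams((225, 150, 170), (18, 22, 18), 1.5, 6.0, 0.4),
    "long_like": TextureParams((160, 120, 185), (22, 18, 24), 4.0, 12.0, 0.6),
    "neutral": TextureParams((192, 135, 178), (20, 20, 21), 2.5, 9.0, 0.5),
    "papillary_like": TextureParams((230, 160, 165), (16, 20, 16), 1.2, 5.0, 0.35),
    "solid_like": TextureParams((150, 115, 190), (24, 18, 26), 5.0, 14.0, 0.65),
    "stroma": TextureParams((238, 205, 218), (8, 10, 8), 5.0, 12.0, 0.5),
    "necrosis": TextureParams((120, 90, 75), (14, 12, 10), 3.0, 8.0, 0.5),
    "background": TextureParams((246, 244, 248), (3, 3, 3), 2.0, 6.0, 0.3),
}

#: Minimum separation (8-bit luminance units) between the necrosis texture's
#: mean luminance and that of every tumor texture; guaranteed by construction
#: and asserted in tests so the exclusion classes stay trivially detectable.
NECROSIS_LUMINANCE_MARGIN = 30.0

#: Expected area fraction of each artifact class *when present on a slide*.
#: Necrosis is a fraction of the (pre-necrosis) tumor area; the others are
#: fractions of the whole slide. The realised fraction per occurrence is
#: uniform in ±30 % of the nominal value, so the nominal value is the mean.
ARTIFACT_NOMINAL_FRACTION = {
    "necrosis": 0.10,
    "fold": 0.04,
    "blur": 0.05,
    "whitespace": 0.04,
}

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a virtual cohort; generation is pure in this object."""

    n_short_patients: int = 17
    n_long_patients: int = 13
    slides_per_patient: tuple[int, int] = (2, 13)
    slide_size_px: tuple[int, int] = (384, 384)
    resolution_um_per_px: float = 2.0
    mixture_bias: float = 0.6
    baseline_fraction: float = 0.15
    mixture_alpha: float = 60.0
    contrast: float = 1.0
    tumor_cover: tuple[float, float] = (0.20, 0.70)
    artifact_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "necrosis": 0.30,
            "fold": 0.15,
            "blur": 0.10,
            "whitespace": 0.10,
        }
    )
    patient_prefix: str = "P"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_short_patients < 1 or self.n_long_patients < 1:
            raise MetadataError("each outcome group needs at least one patient")
        lo, hi = self.slides_per_patient
        if not (1 <= lo <= hi):
            raise MetadataError(f"bad slides_per_patient range {self.slides_per_patient}")
        if not 0.0 <= self.mixture_bias <= 1.0:
            raise MetadataError("mixture_bias must be in [0, 1]")
        if self.baseline_fraction * 2 + self.mixture_bias > 1.0 + 1e-9:
            raise MetadataError("2*baseline_fraction + mixture_bias must be <= 1")
        for k, v in self.artifact_rates.items():
            if k not in ARTIFACT_NOMINAL_FRACTION:
                raise MetadataError(f"unknown artifact class {k!r}")
            if not 0.0 <= v <= 1.0:
                raise MetadataError(f"artifact rate {k}={v} outside [0, 1]")
        if self.resolution_um_per_px <= 0:
            raise MetadataError("resolution must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-slide oracle masks and the true texture mixture proportions.

    ``masks`` holds the partition classes {tumor, necrosis, stroma, artifact,
    background} plus the planted texture subsets of tumor (short_like,
    long_like, neutral). ``proportions`` are fractions of final tumor area.
    """

    slide_id: str
    masks: dict[str, np.ndarray]
    proportions: dict[str, float]

    def partition_classes(self) -> list[str]:
        return ["tumor", "necrosis", "stroma", "artifact", "background"]


@dataclass
class CohortData:
    spec: CohortSpec
    slides: list[SlideImage]
    truth: dict[str, GroundTruth]
    labels: dict[str, OutcomeLabel]
    slide_to_patient: dict[str, str]

    @property
    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": pid,
                "slide_id": sid,
                "group": self.labels[pid].group.value,
                "pfi_months": self.labels[pid].pfi_months,
            }
            for sid, pid in sorted(self.slide_to_patient.items())
        ]
        return pd.DataFrame(rows)

    @property
    def truth_table(self) -> pd.DataFrame:
        rows = []
        for sid in sorted(self.truth):
            gt = self.truth[sid]
            rows.append({"slide_id": sid, **gt.proportions})
        return pd.DataFrame(rows)

    def tumor_mask(self, slide_id: str) -> ClassMask:
        return ClassMask(slide_id, "tumor", self.truth[slide_id].masks["tumor"])

    def outcome_of_slide(self, slide_id: str) -> Outcome:
        return self.labels[self.slide_to_patient[slide_id]].group


def make_validation_spec(**overrides) -> CohortSpec:
    """A 22-patient, one-slide-per-patient spec shaped like the held-out
    validation design (11 PFI_S vs 11 PFI_L)."""
    base = dict(
        n_short_patients=11,
        n_long_patients=11,
        slides_per_patient=(1, 1),
        patient_prefix="T",
    )
    base.update(overrides)
    return CohortSpec(**base)


# ---------------------------------------------------------------------------
# Texture rendering
# ---------------------------------------------------------------------------


def texture_params(name: str, contrast: float = 1.0) -> TextureParams:
    """Palette parameters for ``name`` at the given class contrast.

    ``contrast`` linearly shrinks short_like and long_like toward their
    common midpoint; at 0 the two are parameter-identical by construction.
    Other palette entries are unaffected.
    """
    if name not in TEXTURE_PALETTE:
        raise KeyError(f"unknown texture {name!r}; palette: {sorted(TEXTURE_PALETTE)}")
    p = TEXTURE_PALETTE[name]
    if name not in ("short_like", "long_like") or contrast >= 1.0:
        return p
    a, b = TEXTURE_PALETTE["short_like"], TEXTURE_PALETTE["long_like"]

    def mid(f):
        return tuple((np.asarray(getattr(a, f)) + np.asarray(getattr(b, f))) / 2.0)

    anchor = TextureParams(
        mid("base_rgb"),
        mid("amp_rgb"),
        (a.sigma_fine + b.sigma_fine) / 2,
        (a.sigma_coarse + b.sigma_coarse) / 2,
        (a.w_coarse + b.w_coarse) / 2,
    )

    def blend(f):
        va, vm = np.asarray(getattr(p, f), dtype=float), np.asarray(getattr(anchor, f), dtype=float)
        out = vm + contrast * (va - vm)
        return tuple(out) if out.ndim else float(out)

    return TextureParams(
        blend("base_rgb"),
        blend("amp_rgb"),
        float(blend("sigma_fine")),
        float(blend("sigma_coarse")),
        float(blend("w_coarse")),
    )


def _unit_noise(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def render_texture(
    shape: tuple[int, int],
    name: str,
    rng: np.random.Generator,
    contrast: float = 1.0,
) -> np.ndarray:
    """Render a stationary texture field as an H×W×3 uint8 raster."""
    p = texture_params(name, contrast)
    fine = _unit_noise(shape, p.sigma_fine, rng)
    coarse = _unit_noise(shape, p.sigma_coarse, rng)
    fld = (1.0 - p.w_coarse) * fine + p.w_coarse * coarse
    grain = rng.standard_normal(shape + (3,)) * 2.0
    img = (
        np.asarray(p.base_rgb)[None, None, :]
        + fld[..., None] * np.asarray(p.amp_rgb)[None, None, :]
        + grain
    )
    return np.clip(img, 0, 255).astype(np.uint8)


def texture_mean_luminance(name: str) -> float:
    return float(np.dot(TEXTURE_PALETTE[name].base_rgb, _LUMA))


# ---------------------------------------------------------------------------
# Slide assembly
# ---------------------------------------------------------------------------


def _top_fraction_mask(
    field: np.ndarray, within: np.ndarray, n_pixels: int
) -> np.ndarray:
    """Boolean mask of the ``n_pixels`` largest field values inside ``within``."""
    out = np.zeros(field.shape, dtype=bool)
    n_pixels = int(min(n_pixels, within.sum()))
    if n_pixels <= 0:
        return out
    vals = field[within]
    thresh = np.partition(vals, -n_pixels)[-n_pixels]
    cand = within & (field >= thresh)
    # Ties can overshoot by a handful of pixels; trim deterministically.
    idx = np.flatnonzero(cand.ravel())
    if idx.size > n_pixels:
        order = np.argsort(field.ravel()[idx], kind="stable")[::-1][:n_pixels]
        cand = np.zeros(field.size, dtype=bool)
        cand[idx[order]] = True
        cand = cand.reshape(field.shape)
    out |= cand
    return out


def _band_mask(shape: tuple[int, int], frac: float, rng: np.random.Generator) -> np.ndarray:
    """A straight band through a random point at a random angle covering
    approximately ``frac`` of the raster (exact by distance quantile)."""
    h, w = shape
    theta = rng.uniform(0, np.pi)
    r0, c0 = rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.abs((rr - r0) * np.cos(theta) + (cc - c0) * np.sin(theta))
    t = np.quantile(dist, frac)
    return dist <= t


def inject_artifacts(
    pixels: np.ndarray,
    masks: dict[str, np.ndarray],
    rates: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Stamp nuisance classes onto a rendered slide.

    Artifacts overwrite the underlying texture and evict every other class
    from the pixels they claim, so the ground-truth partition is preserved.
    Necrosis is carved out of tumor; fold/blur/whitespace can fall anywhere.
    Returns the modified raster and mask dict (copies).
    """
    pixels = pixels.copy()
    masks = {k: v.copy() for k, v in masks.items()}
    shape = pixels.shape[:2]
    masks.setdefault("artifact", np.zeros(shape, dtype=bool))
    masks.setdefault("necrosis", np.zeros(shape, dtype=bool))

    def realised(name: str) -> float:
        return ARTIFACT_NOMINAL_FRACTION[name] * rng.uniform(0.7, 1.3)

    def evict(region: np.ndarray, claimed_by: str) -> None:
        for k in masks:
            if k != claimed_by:
                masks[k] &= ~region

    if rng.random() < rates.get("necrosis", 0.0) and masks["tumor"].any():
        frac = realised("necrosis")
        fld = _unit_noise(shape, min(shape) / 10, rng)
        n = int(round(frac * masks["tumor"].sum()))
        region = _top_fraction_mask(fld, masks["tumor"], n)
        if region.any():
            pixels[region] = render_texture(shape, "necrosis", rng)[region]
            evict(region, "necrosis")
            masks["necrosis"] |= region

    if rng.random() < rates.get("whitespace", 0.0):
        fld = _unit_noise(shape, min(shape) / 8, rng)
        n = int(round(realised("whitespace") * pixels[..., 0].size))
        region = _top_fraction_mask(fld, np.ones(shape, dtype=bool), n)
        pixels[region] = render_texture(shape, "background", rng)[region]
        evict(region, "artifact")
        masks["artifact"] |= region

    if rng.random() < rates.get("fold", 0.0):
        region = _band_mask(shape, realised("fold"), rng)
        shade = pixels[region].astype(float) * 0.45
        pixels[region] = np.clip(shade, 0, 255).astype(np.uint8)
        evict(region, "artifact")
        masks["artifact"] |= region

    if rng.random() < rates.get("blur", 0.0):
        fld = _unit_noise(shape, min(shape) / 8, rng)
        n = int(round(realised("blur") * pixels[..., 0].size))
        region = _top_fraction_mask(fld, np.ones(shape, dtype=bool), n)
        blurred = np.stack(
            [ndimage.gaussian_filter(pixels[..., c].astype(float), 6.0) for c in range(3)],
            axis=-1,
        )
        pixels[region] = np.clip(blurred[region], 0, 255).astype(np.uint8)
        evict(region, "artifact")
        masks["artifact"] |= region

    return pixels, masks


def _make_slide(
    spec: CohortSpec,
    slide_id: str,
    patient_id: str,
    group: Outcome,
    rng: np.random.Generator,
) -> tuple[SlideImage, GroundTruth]:
    h, w = spec.slide_size_px
    shape = (h, w)
    n_px = h * w

    # Tissue footprint and tumor blobs by quantile-thresholded smooth noise.
    tissue_frac = rng.uniform(0.75, 0.92)
    tissue = _top_fraction_mask(
        _unit_noise(shape, min(shape) / 4, rng), np.ones(shape, bool), int(tissue_frac * n_px)
    )
    tumor_target = rng.uniform(*spec.tumor_cover)
    tumor_px = int(min(tumor_target * n_px, 0.85 * tissue.sum()))
    tumor = _top_fraction_mask(_unit_noise(shape, min(shape) / 6, rng), tissue, tumor_px)
    # Drop specks so tumor regions have annotation-like granularity.
    lab, nlab = ndimage.label(tumor, structure=np.ones((3, 3), dtype=int))
    if nlab > 1:
        sizes = ndimage.sum_labels(tumor, lab, index=np.arange(1, nlab + 1))
        keep = np.flatnonzero(sizes >= max(64, 0.003 * n_px)) + 1
        if keep.size:
            tumor = np.isin(lab, keep)

    # Per-slide texture mixture: outcome-concordant texture over-represented.
    b, bias = spec.baseline_fraction, spec.mixture_bias
    if group is Outcome.PFI_S:
        mean = np.array([b + bias, b, max(1.0 - 2 * b - bias, 0.0)])
    else:
        mean = np.array([b, b + bias, max(1.0 - 2 * b - bias, 0.0)])
    mean = np.clip(mean, 0.02, None)
    mean /= mean.sum()
    props = rng.dirichlet(spec.mixture_alpha * mean)

    assign_field = _unit_noise(shape, min(shape) / 8, rng)
    flat_tumor = np.flatnonzero(tumor.ravel())
    tumor_idx = flat_tumor[np.argsort(assign_field.ravel()[flat_tumor], kind="stable")]
    counts = np.floor(props * tumor_idx.size).astype(int)
    counts[2] = tumor_idx.size - counts[0] - counts[1]
    class_order = rng.permutation(3)
    texture_masks = {
        "short_like": np.zeros(shape, bool),
        "long_like": np.zeros(shape, bool),
        "neutral": np.zeros(shape, bool),
    }
    names = ["short_like", "long_like", "neutral"]
    start = 0
    for ci in class_order:
        n = counts[ci]
        flat = np.zeros(n_px, bool)
        flat[tumor_idx[start : start + n]] = True
        texture_masks[names[ci]] = flat.reshape(shape)
        start += n

    # Render: background canvas, then stroma, then tumor textures.
    pixels = render_texture(shape, "background", rng)
    stroma = tissue & ~tumor
    pixels[stroma] = render_texture(shape, "stroma", rng)[stroma]
    for name in names:
        m = texture_masks[name]
        if m.any():
            pixels[m] = render_texture(shape, name, rng, contrast=spec.contrast)[m]

    masks = {
        "tumor": tumor,
        "stroma": stroma,
        "necrosis": np.zeros(shape, bool),
        "artifact": np.zeros(shape, bool),
        **texture_masks,
    }
    pixels, masks = inject_artifacts(pixels, masks, spec.artifact_rates, rng)
    masks["background"] = ~(
        masks["tumor"] | masks["stroma"] | masks["necrosis"] | masks["artifact"]
    )

    tum_area = max(int(masks["tumor"].sum()), 1)
    proportions = {
        "p_short_like": float((masks["short_like"] & masks["tumor"]).sum()) / tum_area,
        "p_long_like": float((masks["long_like"] & masks["tumor"]).sum()) / tum_area,
        "p_neutral": float((masks["neutral"] & masks["tumor"]).sum()) / tum_area,
        "tumor_frac_of_slide": masks["tumor"].sum() / n_px,
    }
    slide = SlideImage(slide_id, patient_id, pixels, spec.resolution_um_per_px)
    return slide, GroundTruth(slide_id, masks, proportions)


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate the full virtual cohort described by ``spec``.

    Deterministic: the same spec yields byte-identical slides. Patient-level
    draws (slide counts, PFI months) use one stream; each slide's pixels use
    a stream keyed by the slide's position in the cohort.
    """
    master = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 7]))
    slides: list[SlideImage] = []
    truth: dict[str, GroundTruth] = {}
    labels: dict[str, OutcomeLabel] = {}
    slide_to_patient: dict[str, str] = {}

    lo, hi = spec.slides_per_patient
    groups = [(Outcome.PFI_S, spec.n_short_patients, "S"), (Outcome.PFI_L, spec.n_long_patients, "L")]
    gidx = 0
    for group, n_pat, tag in groups:
        for p in range(n_pat):
            pid = f"{spec.patient_prefix}{tag}{p + 1:02d}"
            n_slides = int(master.integers(lo, hi + 1))
            pfi = (
                float(np.round(master.uniform(0.0, 6.0), 1))
                if group is Outcome.PFI_S
                else float(np.round(master.uniform(18.0, 80.0), 1))
            )
            labels[pid] = OutcomeLabel(pid, group, pfi)
            for k in range(n_slides):
                sid = f"{pid}-{k + 1:02d}"
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 1000 + gidx])
                )
                slide, gt = _make_slide(spec, sid, pid, group, rng)
                slides.append(slide)
                truth[sid] = gt
                slide_to_patient[sid] = pid
                gidx += 1
    return CohortData(spec, slides, truth, labels, slide_to_patient)


# ---------------------------------------------------------------------------
# On-disk cohort layout (used by the numbered analysis drivers)
# ---------------------------------------------------------------------------


def _write_bool_png(mask: np.ndarray, path: Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, mask.astype(np.uint8) * 255)


def write_cohort(cohort: CohortData, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "slides").mkdir(parents=True, exist_ok=True)
    gt_dir = outdir / "ground_truth"
    gt_dir.mkdir(parents=True, exist_ok=True)
    for slide in cohort.slides:
        write_slide(slide, outdir / "slides" / f"{slide.slide_id}.png")
        gt = cohort.truth[slide.slide_id]
        for cls, m in gt.masks.items():
            _write_bool_png(m, gt_dir / f"{slide.slide_id}.{cls}.png")
    write_cohort_table(
        list(cohort.labels.values()), cohort.slide_to_patient, outdir / "metadata.csv"
    )
    cohort.truth_table.to_csv(outdir / "truth.csv", index=False)
    return outdir


def load_cohort(directory: str | Path) -> CohortData:
    """Reload a cohort written by :func:`write_cohort` (spec is not restored;
    a default spec carrying only the slide resolution is attached)."""
    directory = Path(directory)
    meta = read_cohort_table(directory / "metadata.csv")
    slides = []
    truth = {}
    labels: dict[str, OutcomeLabel] = {}
    slide_to_patient: dict[str, str] = {}
    gt_dir = directory / "ground_truth"
    classes = ["tumor", "necrosis", "stroma", "artifact", "background", "short_like", "long_like", "neutral"]
    for _, row in meta.iterrows():
        sid, pid = str(row["slide_id"]), str(row["patient_id"])
        slide = read_slide(directory / "slides" / f"{sid}.png")
        slides.append(slide)
        slide_to_patient[sid] = pid
        pfi = row.get("pfi_months")
        pfi = None if pfi is None or pd.isna(pfi) else float(pfi)
        labels[pid] = OutcomeLabel(pid, Outcome.parse(row["group"]), pfi)
        masks = {}
        for cls in classes:
            p = gt_dir / f"{sid}.{cls}.png"
            if p.exists():
                masks[cls] = read_mask(p, sid, "tumor").mask
        tum = max(int(masks["tumor"].sum()), 1)
        props = {
            "p_short_like": float((masks.get("short_like", np.zeros_like(masks["tumor"])) & masks["tumor"]).sum()) / tum,
            "p_long_like": float((masks.get("long_like", np.zeros_like(masks["tumor"])) & masks["tumor"]).sum()) / tum,
            "p_neutral": float((masks.get("neutral", np.zeros_like(masks["tumor"])) & masks["tumor"]).sum()) / tum,
            "tumor_frac_of_slide": masks["tumor"].sum() / masks["tumor"].size,
        }
        truth[sid] = GroundTruth(sid, masks, props)
    res = slides[0].resolution_um_per_px if slides else 2.0
    spec = CohortSpec(resolution_um_per_px=res)
    return CohortData(spec, slides, truth, labels, slide_to_patient)
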