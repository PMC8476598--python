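"""Core data model for slides, masks and physical geometry.

A slide is a plain dense RGB raster with a physical resolution in µm/pixel;
masks are dense binary rasters congruent with the slide. Virtual slides are
small enough (≲ 2000×2000 px) that nothing here needs tiling or pyramids.

Coordinates are 0-based ``(row, col)``. Field-of-view sizes are given in
micrometers and converted to pixels through the slide resolution, mirroring
how scanner-native resolutions (0.22–0.24 µm/px in clinical scanners) relate
to the physical context window a patch classifier sees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CLINICAL_SCANNER_RESOLUTIONS_UM",
    "MASK_CLASSES",
    "ClassMask",
    "FieldOfView",
    "GeometryError",
    "MaskError",
    "MetadataError",
    "Outcome",
    "OutcomeLabel",
    "Patch",
    "SlideImage",
    "UndefinedDenominatorError",
    "area_percent",
    "extract_patches",
    "fov_to_pixels",
    "grid_centers",
    "read_cohort_table",
    "read_mask",
    "read_slide",
    "write_cohort_table",
    "write_mask",
    "write_slide",
    "read_score_table",
    "write_score_table",
]

#: Resolutions of the two clinical whole-slide scanners the workflow was
#: designed around; kept as constants for worked examples and docs. Synthetic
#: slides typically use a coarser resolution (2–4 µm/px).
CLINICAL_SCANNER_RESOLUTIONS_UM = (0.22, 0.24)

MASK_CLASSES = (
    "tumor",
    "dbm_short",
    "dbm_long",
    "necrosis",
    "stroma",
    "artifact",
    "background",
)

SCORE_COLUMNS = [
    "slide_id",
    "long_dbm_pct",
    "short_dbm_pct",
    "ratio",
    "outcome",
    "prediction",
]


class GeometryError(ValueError):
    """Non-positive or otherwise impossible physical geometry."""


class MaskError(ValueError):
    """Mask/raster shape mismatch or class-constraint violation."""


class UndefinedDenominatorError(ZeroDivisionError):
    """Area percentage requested against an empty reference mask."""


class MetadataError(ValueError):
    """Missing or invalid slide/cohort metadata (never silently defaulted)."""


class Outcome(str, Enum):
    """Platinum-free-interval outcome group.

    PFI_S: recurrence within 6 months of the last platinum cycle
    (platinum-resistant extreme); PFI_L: recurrence-free for at least
    18 months (platinum-sensitive extreme).
    """

    PFI_S = "PFI_S"
    PFI_L = "PFI_L"

    @classmethod
    def parse(cls, value: str) -> "Outcome":
        v = str(value).strip().upper().replace("-", "_")
        aliases = {"SHORT": "PFI_S", "LONG": "PFI_L", "S": "PFI_S", "L": "PFI_L"}
        v = aliases.get(v, v)
        try:
            return cls(v)
        except ValueError as exc:
            raise MetadataError(f"unknown outcome label {value!r}") from exc


@dataclass(frozen=True)
class SlideImage:
    """An RGB raster with physical resolution and slide/patient identity."""

    slide_id: str
    patient_id: str
    pixels: np.ndarray
    resolution_um_per_px: float

    def __post_init__(self) -> None:
        if self.resolution_um_per_px <= 0:
            raise GeometryError(
                f"resolution must be positive, got {self.resolution_um_per_px}"
            )
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[-1] != 3 or px.size == 0:
            raise MaskError(f"expected an H×W×3 raster, got shape {px.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ClassMask:
    """A binary per-pixel mask of one tissue class, congruent with its slide."""

    slide_id: str
    class_name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.class_name not in MASK_CLASSES:
            raise MaskError(
                f"unknown mask class {self.class_name!r}; expected one of {MASK_CLASSES}"
            )
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise MaskError(f"mask must be 2-D, got shape {m.shape}")
        if m.dtype != bool:
            object.__setattr__(self, "mask", m.astype(bool))

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def require_congruent(self, other: "ClassMask | SlideImage") -> None:
        other_shape = other.shape if isinstance(other, SlideImage) else other.mask.shape
        if tuple(self.mask.shape) != tuple(other_shape):
            raise MaskError(
                f"mask shape {self.mask.shape} not congruent with {tuple(other_shape)}"
            )


@dataclass(frozen=True)
class OutcomeLabel:
    """Outcome group of one patient, with optional PFI in months."""

    patient_id: str
    group: Outcome
    pfi_months: float | None = None

    def __post_init__(self) -> None:
        if self.pfi_months is None:
            return
        if self.pfi_months < 0:
            raise MetadataError("pfi_months must be non-negative")
        if self.group is Outcome.PFI_S and self.pfi_months > 6:
            raise MetadataError(
                f"{self.patient_id}: PFI_S requires pfi_months <= 6, got {self.pfi_months}"
            )
        if self.group is Outcome.PFI_L and self.pfi_months < 18:
            raise MetadataError(
                f"{self.patient_id}: PFI_L requires pfi_months >= 18, got {self.pfi_months}"
            )


def fov_to_pixels(fov_um: float, resolution_um_per_px: float) -> int:
    """Convert a physical field of view to a pixel length.

    Rounded to the nearest pixel, never below 1. E.g. a 200 µm context at the
    0.22 µm/px scanner resolution is 909 px; at the default synthetic
    resolution of 2.0 µm/px it is exactly 100 px.
    """
    if fov_um <= 0 or resolution_um_per_px <= 0:
        raise GeometryError(
            f"fov_um and resolution must be positive, got ({fov_um}, {resolution_um_per_px})"
        )
    return max(1, int(round(fov_um / resolution_um_per_px)))


@dataclass(frozen=True)
class FieldOfView:
    """A physical context window and its pixel size at a given resolution."""

    fov_um: float
    resolution_um_per_px: float
    patch_px: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "patch_px", fov_to_pixels(self.fov_um, self.resolution_um_per_px)
        )


@dataclass(frozen=True)
class Patch:
    pixels: np.ndarray
    center: tuple[int, int]
    label: str


def grid_centers(shape: tuple[int, int], stride_px: int) -> np.ndarray:
    """Regular grid of candidate patch centers, anchored at stride//2.

    Returns an (n, 2) int array of (row, col). The anchor makes a single
    stride-sized tile on a stride-sized raster center exactly at its middle.
    """
    if stride_px < 1:
        raise GeometryError(f"stride must be >= 1, got {stride_px}")
    rows = np.arange(stride_px // 2, shape[0], stride_px)
    cols = np.arange(stride_px // 2, shape[1], stride_px)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def _cut_patch(pixels: np.ndarray, center: tuple[int, int], size: int) -> np.ndarray:
    """Cut a size×size window centered at ``center``, zero-padded at borders."""
    h, w = pixels.shape[:2]
    r0 = center[0] - size // 2
    c0 = center[1] - size // 2
    out = np.zeros((size, size) + pixels.shape[2:], dtype=pixels.dtype)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = pixels[rs:re, cs:ce]
    return out


def extract_patches(
    slide: SlideImage,
    mask: ClassMask,
    fov: FieldOfView,
    stride_px: int,
) -> list[Patch]:
    """Tile the slide with FOV-sized patches whose centers lie inside ``mask``.

    Border patches are zero-padded so area accounting stays exact at slide
    edges; an empty mask yields an empty list rather than an error.
    """
    mask.require_congruent(slide)
    centers = grid_centers(slide.shape, stride_px)
    keep = mask.mask[centers[:, 0], centers[:, 1]]
    return [
        Patch(
            pixels=_cut_patch(slide.pixels, (int(r), int(c)), fov.patch_px),
            center=(int(r), int(c)),
            label=mask.class_name,
        )
        for r, c in centers[keep]
    ]


def area_percent(part: ClassMask, whole: ClassMask) -> float:
    """Percent of ``whole``'s area occupied by ``part`` (``part`` ⊆ ``whole``).

    This is the quantity reported per slide for each digital-biomarker class:
    percent of total tumor area. An empty reference mask raises rather than
    silently returning 0, so the slide can be flagged upstream.
    """
    part.require_congruent(whole)
    if np.any(part.mask & ~whole.mask):
        raise MaskError(
            f"{part.class_name} mask is not a subset of {whole.class_name} mask"
        )
    denom = whole.area_px
    if denom == 0:
        raise UndefinedDenominatorError(
            f"slide {whole.slide_id}: empty {whole.class_name} reference mask"
        )
    return 100.0 * part.area_px / denom


# ---------------------------------------------------------------------------
# Raster and table I/O.
#
# Rasters are PNG or TIFF; physical resolution and identity travel in a JSON
# sidecar ("<file>.json") because PNG has no reliable physical-unit tag and a
# sidecar keeps both formats symmetric. A missing sidecar is an error — the
# resolution is never silently defaulted.
# ---------------------------------------------------------------------------

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_slide(slide: SlideImage, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise MetadataError(f"unsupported raster format {path.suffix!r}")
    iio.imwrite(path, np.ascontiguousarray(slide.pixels.astype(np.uint8)))
    _sidecar(path).write_text(
        json.dumps(
            {
                "slide_id": slide.slide_id,
                "patient_id": slide.patient_id,
                "resolution_um_per_px": slide.resolution_um_per_px,
            },
            indent=2,
        )
    )
    return path


def read_slide(path: str | Path) -> SlideImage:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise MetadataError(
            f"{path}: no resolution sidecar {side.name}; refusing to guess µm/px"
        )
    meta = json.loads(side.read_text())
    if "resolution_um_per_px" not in meta:
        raise MetadataError(f"{side}: sidecar lacks 'resolution_um_per_px'")
    return SlideImage(
        slide_id=meta.get("slide_id", path.stem),
        patient_id=meta.get("patient_id", ""),
        pixels=np.asarray(iio.imread(path)),
        resolution_um_per_px=float(meta["resolution_um_per_px"]),
    )


def write_mask(mask: ClassMask, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (mask.mask.astype(np.uint8) * 255))
    return path


def read_mask(path: str | Path, slide_id: str, class_name: str) -> ClassMask:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return ClassMask(slide_id=slide_id, class_name=class_name, mask=arr > 127)


def write_cohort_table(labels: Sequence[OutcomeLabel], slide_map: dict[str, str], path: str | Path) -> Path:
    """Write the cohort metadata CSV: one row per slide.

    ``slide_map`` maps slide_id → patient_id.
    """
    by_patient = {lab.patient_id: lab for lab in labels}
    rows = []
    for slide_id in sorted(slide_map):
        pid = slide_map[slide_id]
        lab = by_patient[pid]
        rows.append(
            {
                "patient_id": pid,
                "slide_id": slide_id,
                "group": lab.group.value,
                "pfi_months": "" if lab.pfi_months is None else lab.pfi_months,
            }
        )
    pd.DataFrame(rows, columns=["patient_id", "slide_id", "group", "pfi_months"]).to_csv(
        path, index=False
    )
    return Path(path)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort metadata CSV.

    Raises :class:`MetadataError` naming the offending row on an unknown
    outcome label or a PFI inconsistent with its group.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "slide_id": str})
    required = {"patient_id", "slide_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    if df["slide_id"].duplicated().any():
        dup = df.loc[df["slide_id"].duplicated(), "slide_id"].iloc[0]
        raise MetadataError(f"{path}: duplicate slide_id {dup!r}")
    for i, row in df.iterrows():
        try:
            group = Outcome.parse(row["group"])
            pfi = row.get("pfi_months")
            pfi = None if pfi is None or pd.isna(pfi) or pfi == "" else float(pfi)
            OutcomeLabel(str(row["patient_id"]), group, pfi)
        except MetadataError as exc:
            raise MetadataError(f"{path}: row {i} ({row['slide_id']!r}): {exc}") from exc
        df.loc[i, "group"] = group.value
    return df


def write_score_table(rows: Sequence[dict], path: str | Path) -> Path:
    pd.DataFrame(list(rows), columns=SCORE_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"slide_id": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    return df


def iter_slide_files(directory: str | Path) -> Iterator[Path]:
    """Yield raster files (with sidecars) in a cohort directory, sorted."""
    directory = Path(directory)
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in _RASTER_SUFFIXES and _sidecar(p).exists():
            yield p
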