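"""Confidence filtering, minimum-focus component rule, curation, replicates."""

from collections import deque

import numpy as np
import pytest

from wsidbm.slide_core import Outcome
from wsidbm.stage2_weak_outcome import ConfidenceMap
from wsidbm.stage3_refinement import (
    DigitalBiomarkerMask,
    curate_annotations,
    filter_high_confidence,
    min_focus_area_px,
    remove_small_foci,
    train_refined_model,
)

RES = 2.0  # µm/px in these geometry tests


def bruteforce_min_focus(mask: np.ndarray, min_focus_um: float, res: float) -> np.ndarray:
    """Independent oracle: BFS flood fill with 8-connectivity, then drop
    components below the equivalent-diameter area threshold."""
    mask = mask.astype(bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    out = np.zeros_like(mask)
    min_area = min_focus_area_px(min_focus_um, res)
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = []
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    r, c = q.popleft()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
                if len(comp) >= min_area:
                    for r, c in comp:
                        out[r, c] = True
    return out


def disc_mask(shape, center, diameter_um, res=RES):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r_px = diameter_um / (2 * res)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r_px**2


def conf_from_mask(short_mask, long_conf_mask=None, slide_id="s1"):
    """Build a ConfidenceMap with conf_short = 0.95 on short_mask, 0.05 off."""
    tumor = np.ones(short_mask.shape, dtype=bool)
    cs = np.where(short_mask, 0.95, 0.05)
    return ConfidenceMap(slide_id, cs, 1.0 - cs, tumor)


class TestMinFocusFilter:
    def test_equivalence_with_bruteforce_flood_fill(self):
        """scipy-based component filtering equals BFS flood fill on random
        small masks across several size thresholds."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            h, w = rng.integers(4, 33, size=2)
            mask = rng.random((h, w)) < rng.uniform(0.2, 0.6)
            min_um = rng.choice([4.0, 8.0, 12.0, 20.0])
            got = remove_small_foci(mask, min_um, RES)
            want = bruteforce_min_focus(mask, min_um, RES)
            assert np.array_equal(got, want), f"trial {trial}"

    def test_size_rule_on_known_discs(self):
        """150 µm and 250 µm foci at a 200 µm minimum: only the larger one
        survives."""
        shape = (300, 300)
        small = disc_mask(shape, (70, 70), 150)
        large = disc_mask(shape, (200, 200), 250)
        kept = remove_small_foci(small | large, 200.0, RES)
        assert not (kept & small).any()
        assert (kept & large).sum() == large.sum()

    def test_threshold_is_inclusive_on_equivalent_diameter(self):
        # a component with area exactly the minimum survives (>= rule)
        area = int(np.ceil(min_focus_area_px(20.0, RES)))
        mask = np.zeros((100, 100), dtype=bool)
        mask.ravel()[:area] = True  # one 8-connected strip... make it a block
        mask[:] = False
        side = int(np.ceil(np.sqrt(area)))
        mask[:side, :side] = True
        kept = remove_small_foci(mask, 20.0, RES)
        assert kept.sum() == mask.sum()


class TestFilterHighConfidence:
    def test_unreachable_threshold_gives_empty_masks(self):
        cm = conf_from_mask(np.ones((50, 50), dtype=bool))
        s, l = filter_high_confidence(cm, 1.0, 10.0, RES)
        assert s.area_px == 0 and l.area_px == 0

    def test_raising_threshold_never_grows_masks(self):
        rng = np.random.default_rng(5)
        conf = rng.random((80, 80))
        cm = ConfidenceMap("s1", conf, 1 - conf, np.ones((80, 80), bool))
        areas = []
        for t in (0.6, 0.7, 0.8, 0.9):
            s, l = filter_high_confidence(cm, t, 4.0, RES)
            areas.append((s.area_px, l.area_px))
        assert [a[0] for a in areas] == sorted([a[0] for a in areas], reverse=True)
        assert [a[1] for a in areas] == sorted([a[1] for a in areas], reverse=True)

    def test_idempotence(self):
        """Re-filtering the filter's own output changes nothing."""
        rng = np.random.default_rng(6)
        conf = rng.random((60, 60))
        cm = ConfidenceMap("s1", conf, 1 - conf, np.ones((60, 60), bool))
        s1, l1 = filter_high_confidence(cm, 0.8, 10.0, RES)
        cm2 = ConfidenceMap(
            "s1",
            np.where(s1.mask, 0.99, 0.0),
            np.where(l1.mask, 0.99, 0.0),
            cm.tumor_mask,
        )
        s2, l2 = filter_high_confidence(cm2, 0.8, 10.0, RES)
        assert np.array_equal(s2.mask, s1.mask)
        assert np.array_equal(l2.mask, l1.mask)

    def test_masks_disjoint_and_inside_tumor(self):
        rng = np.random.default_rng(7)
        conf = rng.random((60, 60))
        tumor = rng.random((60, 60)) > 0.3
        cm = ConfidenceMap("s1", np.where(tumor, conf, np.nan), np.where(tumor, 1 - conf, np.nan), tumor)
        s, l = filter_high_confidence(cm, 0.7, 4.0, RES)
        assert not (s.mask & l.mask).any()
        assert not (s.mask & ~tumor).any()
        assert not (l.mask & ~tumor).any()

    def test_invalid_threshold_rejected(self):
        cm = conf_from_mask(np.ones((10, 10), bool))
        for bad in (0.5, 0.0, 1.1):
            with pytest.raises(ValueError):
                filter_high_confidence(cm, bad, 10.0, RES)


class TestCuration:
    def _dbm(self, mask, min_um=200.0):
        return DigitalBiomarkerMask("s1", "dbm_short", mask, 0.9, min_um)

    def test_empty_exclusions_identity(self):
        mask = disc_mask((300, 300), (150, 150), 250)
        (out,) = curate_annotations([self._dbm(mask)], [], RES)
        assert np.array_equal(out.mask, mask)

    def test_component_inside_necrosis_removed(self):
        mask = disc_mask((300, 300), (150, 150), 250)
        necrosis = disc_mask((300, 300), (150, 150), 400)
        (out,) = curate_annotations([self._dbm(mask)], [necrosis], RES)
        assert out.area_px == 0

    def test_fragmentation_reapplies_min_focus(self):
        """An artifact band splits a focus into a 120 µm and a 260 µm piece;
        only the large fragment survives re-filtering."""
        shape = (400, 200)
        mask = np.zeros(shape, dtype=bool)
        # two rectangles joined by the band region; widths chosen so the
        # fragments have equivalent diameters ~120 µm and ~260 µm at 2 µm/px
        area_small = int(np.pi * (120 / (2 * RES)) ** 2 * 0.9)  # below 200 µm
        area_large = int(np.pi * (260 / (2 * RES)) ** 2)  # above 200 µm
        h_small = area_small // 100
        h_large = area_large // 100
        mask[10 : 10 + h_small, 50:150] = True
        band_start = 10 + h_small
        mask[band_start : band_start + 10, 50:150] = True
        mask[band_start + 10 : band_start + 10 + h_large, 50:150] = True
        artifact = np.zeros(shape, dtype=bool)
        artifact[band_start : band_start + 10, :] = True
        (out,) = curate_annotations([self._dbm(mask)], [artifact], RES)
        # oracle: brute-force components of the subtracted mask
        want = bruteforce_min_focus(mask & ~artifact, 200.0, RES)
        assert np.array_equal(out.mask, want)
        assert out.area_px == h_large * 100


@pytest.fixture(scope="module")
def curated(tiny_cohort):
    """Oracle-derived biomarker annotations (planted textures inside tumor),
    bypassing stages 1–2 to isolate stage 3."""
    out = {}
    for s in tiny_cohort.slides:
        gt = tiny_cohort.truth[s.slide_id].masks
        out[s.slide_id] = [
            DigitalBiomarkerMask(s.slide_id, "dbm_short", gt["short_like"], 0.9, 100.0),
            DigitalBiomarkerMask(s.slide_id, "dbm_long", gt["long_like"], 0.9, 100.0),
        ]
    return out


class TestRefinedModel:
    def test_replicates_agree_on_confident_pixels(self, tiny_cohort, tiny_holdout, curated):
        models = train_refined_model(
            tiny_cohort.slides, curated, seeds=(0, 1), call_threshold=0.75
        )
        assert [m.replicate_id for m in models] == [1, 2]
        agree = confident = 0
        for s in tiny_holdout.slides:
            c1 = models[0].confidence_maps(s)
            c2 = models[1].confidence_maps(s)
            conf_px = (np.maximum(c1["dbm_short"], c1["dbm_long"]) >= 0.75) & (
                np.maximum(c2["dbm_short"], c2["dbm_long"]) >= 0.75
            )
            same = (c1["dbm_short"] >= 0.75) == (c2["dbm_short"] >= 0.75)
            agree += (same & conf_px).sum()
            confident += conf_px.sum()
        assert confident > 0
        assert agree / confident >= 0.9

    def test_same_seed_bit_identical(self, tiny_cohort, curated):
        a = train_refined_model(tiny_cohort.slides, curated, seeds=(7,))
        b = train_refined_model(tiny_cohort.slides, curated, seeds=(7,))
        s = tiny_cohort.slides[0]
        np.testing.assert_array_equal(
            a[0].confidence_maps(s)["dbm_short"], b[0].confidence_maps(s)["dbm_short"]
        )

    def test_planted_texture_recovery(self, tiny_cohort, tiny_holdout, curated):
        """Short-biomarker calls recover the planted short-like texture with
        IoU >= 0.6 on held-out slides."""
        (model,) = train_refined_model(tiny_cohort.slides, curated, seeds=(0,))
        inter = union = 0
        for s in tiny_holdout.slides:
            gt = tiny_holdout.truth[s.slide_id].masks
            conf = model.confidence_maps(s)
            pred = (conf["dbm_short"] >= model.call_threshold) & gt["tumor"]
            true = gt["short_like"] & gt["tumor"]
            inter += (pred & true).sum()
            union += (pred | true).sum()
        assert inter / union >= 0.6

    def test_cohortwide_missing_class_named_in_error(self, tiny_cohort):
        only_short = {
            s.slide_id: [
                DigitalBiomarkerMask(
                    s.slide_id,
                    "dbm_short",
                    tiny_cohort.truth[s.slide_id].masks["short_like"],
                    0.9,
                    100.0,
                )
            ]
            for s in tiny_cohort.slides
        }
        with pytest.raises(ValueError, match="dbm_long"):
            train_refined_model(tiny_cohort.slides, only_short, seeds=(0,))
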