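"""Generator properties: determinism, ground-truth partition, planted bias,
texture separability and artifact statistics."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from wsidbm.learners import patch_features
from wsidbm.slide_core import MetadataError
from wsidbm.synthetic_cohort import (
    ARTIFACT_NOMINAL_FRACTION,
    NECROSIS_LUMINANCE_MARGIN,
    TEXTURE_PALETTE,
    CohortSpec,
    generate_cohort,
    inject_artifacts,
    render_texture,
    texture_mean_luminance,
    texture_params,
)

PARTITION = ["tumor", "necrosis", "stroma", "artifact", "background"]


def small_spec(**kw):
    base = dict(
        n_short_patients=2,
        n_long_patients=2,
        slides_per_patient=(1, 2),
        slide_size_px=(96, 96),
        resolution_um_per_px=8.0,
        seed=5,
    )
    base.update(kw)
    return CohortSpec(**base)


class TestCohortStructure:
    def test_default_spec_mirrors_study_shape(self):
        """Default cohort: 30 patients split 17/13, 2–13 slides per patient.

        Slide size is shrunk here (it does not affect counts) so the check
        stays fast.
        """
        spec = CohortSpec(slide_size_px=(64, 64), resolution_um_per_px=8.0, seed=9)
        cohort = generate_cohort(spec)
        assert len(cohort.labels) == 30
        groups = [lab.group.value for lab in cohort.labels.values()]
        assert groups.count("PFI_S") == 17 and groups.count("PFI_L") == 13
        per_patient = cohort.metadata.groupby("patient_id").size()
        assert per_patient.between(2, 13).all()
        assert 60 <= len(cohort.slides) <= 390

    def test_determinism_byte_identical(self):
        a = generate_cohort(small_spec())
        b = generate_cohort(small_spec())
        assert [s.slide_id for s in a.slides] == [s.slide_id for s in b.slides]
        for sa, sb in zip(a.slides, b.slides):
            assert np.array_equal(sa.pixels, sb.pixels)
        for sid in a.truth:
            for cls in a.truth[sid].masks:
                assert np.array_equal(a.truth[sid].masks[cls], b.truth[sid].masks[cls])

    def test_renaming_patients_leaves_pixels_identical(self):
        a = generate_cohort(small_spec(patient_prefix="P"))
        b = generate_cohort(small_spec(patient_prefix="Q"))
        for sa, sb in zip(a.slides, b.slides):
            assert sa.slide_id != sb.slide_id
            assert np.array_equal(sa.pixels, sb.pixels)

    def test_ground_truth_partitions_every_slide(self):
        cohort = generate_cohort(small_spec())
        for sid, gt in cohort.truth.items():
            total = sum(gt.masks[c].astype(int) for c in PARTITION)
            assert np.all(total == 1), f"{sid}: partition violated"
            tum = gt.masks["tumor"]
            assert tum.any(), f"{sid}: no tumor region"
            for tex in ("short_like", "long_like", "neutral"):
                assert not np.any(gt.masks[tex] & ~tum)
            assert not np.any(gt.masks["short_like"] & gt.masks["long_like"])

    def test_degenerate_spec_rejected(self):
        with pytest.raises(MetadataError):
            CohortSpec(n_short_patients=0)
        with pytest.raises(MetadataError):
            CohortSpec(mixture_bias=1.2)
        with pytest.raises(MetadataError):
            CohortSpec(artifact_rates={"fold": 2.0})

    def test_mixture_bias_separates_groups(self):
        """At bias 0.6 the short-like fraction in PFI_S tumors exceeds that
        in PFI_L tumors by at least 0.4 on average (recomputed from the
        emitted ground-truth masks)."""
        spec = CohortSpec(
            n_short_patients=15,
            n_long_patients=15,
            slides_per_patient=(1, 1),
            slide_size_px=(96, 96),
            resolution_um_per_px=8.0,
            mixture_bias=0.6,
            seed=77,
        )
        cohort = generate_cohort(spec)
        fracs = {"PFI_S": [], "PFI_L": []}
        for sid, gt in cohort.truth.items():
            tum = gt.masks["tumor"].sum()
            frac = (gt.masks["short_like"] & gt.masks["tumor"]).sum() / tum
            fracs[cohort.outcome_of_slide(sid).value].append(frac)
        assert np.mean(fracs["PFI_S"]) - np.mean(fracs["PFI_L"]) >= 0.4


class TestTextures:
    def test_full_contrast_textures_linearly_separable(self):
        """Patch mean/variance features separate short-like from long-like
        with >= 95 % held-out accuracy at contrast 1.0."""
        rng = np.random.default_rng(0)
        X, y = [], []
        for label, name in enumerate(("short_like", "long_like")):
            for _ in range(250):
                patch = render_texture((40, 40), name, rng, contrast=1.0)
                f = patch_features(patch)
                X.append(f[:6])  # means and stds only
                y.append(label)
        Xtr, Xte, ytr, yte = train_test_split(
            np.array(X), np.array(y), test_size=0.4, random_state=0, stratify=y
        )
        acc = LogisticRegression(max_iter=500).fit(Xtr, ytr).score(Xte, yte)
        assert acc >= 0.95

    def test_zero_contrast_collapses_distributions(self):
        """contrast = 0 makes the two planted textures parameter-identical,
        hence byte-identical under the same RNG stream."""
        assert texture_params("short_like", 0.0) == texture_params("long_like", 0.0)
        a = render_texture((32, 32), "short_like", np.random.default_rng(5), contrast=0.0)
        b = render_texture((32, 32), "long_like", np.random.default_rng(5), contrast=0.0)
        assert np.array_equal(a, b)

    def test_necrosis_luminance_margin(self):
        nec = texture_mean_luminance("necrosis")
        for name in ("short_like", "long_like", "neutral", "papillary_like", "solid_like"):
            assert abs(texture_mean_luminance(name) - nec) >= NECROSIS_LUMINANCE_MARGIN

    def test_unknown_texture_rejected(self):
        with pytest.raises(KeyError):
            render_texture((8, 8), "nope", np.random.default_rng(0))

    def test_palette_complete(self):
        assert {"short_like", "long_like", "neutral", "papillary_like", "solid_like"} <= set(
            TEXTURE_PALETTE
        )


class TestArtifacts:
    def _blank(self, shape=(96, 96)):
        px = np.full(shape + (3,), 180, dtype=np.uint8)
        masks = {
            "tumor": np.zeros(shape, bool),
            "stroma": np.ones(shape, bool),
        }
        masks["tumor"][20:70, 20:70] = True
        masks["stroma"] &= ~masks["tumor"]
        return px, masks

    def test_zero_rates_no_artifact_pixels(self):
        px, masks = self._blank()
        out_px, out_masks = inject_artifacts(px, masks, {k: 0.0 for k in ARTIFACT_NOMINAL_FRACTION}, np.random.default_rng(0))
        assert not out_masks["artifact"].any()
        assert not out_masks["necrosis"].any()
        assert np.array_equal(out_px, px)

    def test_fold_rate_one_always_bands(self):
        for seed in range(5):
            px, masks = self._blank()
            _, out = inject_artifacts(px, masks, {"fold": 1.0}, np.random.default_rng(seed))
            assert out["artifact"].any()

    def test_fold_area_fraction_matches_expectation(self):
        """Monte-Carlo: mean fold area fraction over 50 slides within 3 SE of
        rate × nominal fraction."""
        rate, nominal = 0.6, ARTIFACT_NOMINAL_FRACTION["fold"]
        fracs = []
        for seed in range(50):
            px, masks = self._blank()
            _, out = inject_artifacts(px, masks, {"fold": rate}, np.random.default_rng(seed))
            fracs.append(out["artifact"].mean())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - rate * nominal) <= 3 * se

    def test_necrosis_carved_from_tumor(self):
        px, masks = self._blank()
        tumor_before = masks["tumor"].copy()
        _, out = inject_artifacts(px, masks, {"necrosis": 1.0}, np.random.default_rng(2))
        assert out["necrosis"].any()
        assert not np.any(out["necrosis"] & out["tumor"])
        assert np.all(out["necrosis"] <= tumor_before)

    def test_artifacts_preserve_partition(self):
        spec = small_spec(
            artifact_rates={"necrosis": 1.0, "fold": 1.0, "blur": 1.0, "whitespace": 1.0}
        )
        cohort = generate_cohort(spec)
        for gt in cohort.truth.values():
            total = sum(gt.masks[c].astype(int) for c in PARTITION)
            assert np.all(total == 1)
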