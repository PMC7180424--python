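import numpy as np
import pandas as pd
import pytest

from polypscope.evaluation import mean_pairwise_kappa
from polypscope.slide_inference import ThresholdConfig, hierarchical_classify
from polypscope.synthetic import (
    DEFAULT_TEXTURES,
    AnnotatorModel,
    SlideSpec,
    expected_pairwise_kappa,
    generate_cohort,
    generate_slide,
    sample_planted_counts,
    separability_ratio,
    simulate_annotator_panel,
)
from polypscope.wsi_io import PATCH_CLASS_INDEX, SLIDE_CLASSES


class TestTextures:
    def test_default_recipes_are_separable(self):
        """Texture-statistic vectors separate the five classes by well over
        3x the intra-class spread."""
        assert separability_ratio(n_per_class=10, seed=0) > 3.0

    def test_unknown_structure_rejected(self):
        from polypscope.synthetic import TextureSpec

        with pytest.raises(ValueError):
            TextureSpec("TA", (0.5, 0.5, 0.5), 32, "stripes")


class TestGenerateSlide:
    def test_determinism_bit_identical(self):
        spec = SlideSpec("TA", slide_size=(1120, 1120), roi_count=2,
                         villous_fraction=0.2)
        a = generate_slide(spec, seed=9)
        b = generate_slide(spec, seed=9)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.label_mask, b.label_mask)
        assert a.annotations == b.annotations

    def test_zero_villous_fraction_draws_no_tva(self):
        spec = SlideSpec("TA", villous_fraction=0.0)
        slide = generate_slide(spec, seed=1)
        assert (slide.label_mask == PATCH_CLASS_INDEX["TVA"]).sum() == 0

    def test_planted_fraction_recoverable_from_mask(self):
        spec = SlideSpec("TVA", villous_fraction=0.5)
        slide = generate_slide(spec, seed=2)
        assert 0.48 <= slide.area_fraction("TVA") <= 0.52
        assert abs(slide.realized_fraction - 0.5) <= 0.02

    def test_fraction_validity_per_branch(self):
        with pytest.raises(ValueError, match="adenomatous"):
            SlideSpec("HP", villous_fraction=0.3)
        with pytest.raises(ValueError, match="serrated"):
            SlideSpec("TA", ssa_fraction=0.1)

    def test_roi_larger_than_slide_rejected(self):
        with pytest.raises(ValueError, match="exceeds slide"):
            SlideSpec("TA", slide_size=(448, 448), roi_tile_range=(3, 4))

    def test_annotations_tile_the_planted_rois(self):
        spec = SlideSpec("SSA", ssa_fraction=0.25, slide_size=(1568, 1568),
                         roi_count=2)
        slide = generate_slide(spec, seed=3)
        # annotated lesion area == non-NORM mask area, with matching labels
        lesion_area = sum(a.area for a in slide.annotations if a.label != "NORM")
        assert lesion_area == (slide.label_mask != PATCH_CLASS_INDEX["NORM"]).sum()
        for ann in slide.annotations:
            block = slide.label_mask[ann.y0 : ann.y1, ann.x0 : ann.x1]
            assert (block == PATCH_CLASS_INDEX[ann.label]).all()

    def test_oracle_counts_match_tile_labels(self):
        spec = SlideSpec("TA", villous_fraction=0.2)
        slide = generate_slide(spec, seed=4)
        counts = slide.oracle_class_counts()
        tiles = list(slide.tile_labels.values())
        assert counts.n_TA == tiles.count("TA")
        assert counts.n_TVA == tiles.count("TVA")
        assert counts.total == (2048 // 224) ** 2


class TestGenerateCohort:
    def test_counts_and_split_arithmetic(self):
        cohort = generate_cohort(5, split_fractions=(0.6, 0.2, 0.2), seed=0)
        assert len(cohort.records) == 20
        splits = pd.Series([r.split for r in cohort.records]).value_counts()
        assert splits["train"] == 12 and splits["validation"] == 4
        assert splits["test_internal"] == 4
        labels = pd.Series([cohort.true_label(r.slide_id) for r in cohort.records])
        assert (labels.value_counts() == 5).all()

    def test_seeds_change_layout_not_counts(self):
        a = generate_cohort(2, seed=1, slide_size=(1120, 1120), roi_count=2)
        b = generate_cohort(2, seed=2, slide_size=(1120, 1120), roi_count=2)
        assert len(a.records) == len(b.records)
        sa = a.render(a.records[0].slide_id)
        sb = b.render(b.records[0].slide_id)
        assert not np.array_equal(sa.image, sb.image)

    def test_bad_split_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_cohort(2, split_fractions=(0.5, 0.2, 0.2))

    def test_boundary_avoiding_ta_cohort_is_all_ta_under_oracle(self):
        """Planted villous fractions < 0.3 with oracle patch labels give TA
        for every slide under the default thresholds."""
        cohort = generate_cohort({"TA": 4}, split_fractions=(1.0, 0.0, 0.0), seed=5)
        thr = ThresholdConfig()
        for sid in cohort.slide_ids():
            slide = cohort.render(sid)
            assert hierarchical_classify(slide.oracle_class_counts(), thr) == "TA"

    def test_write_produces_loadable_cohort(self, tmp_path):
        from polypscope import wsi_io

        cohort = generate_cohort(1, seed=6, slide_size=(1120, 1120), roi_count=2)
        paths = cohort.write(tmp_path)
        records = wsi_io.read_manifest(paths["manifest"])
        assert len(records) == 4
        anns = wsi_io.read_annotations(paths["annotations"])
        assert {a.slide_id for a in anns} == {r.slide_id for r in records}
        img = wsi_io.read_image(records[0].image_path)
        assert img.shape == (1120, 1120, 3)


class TestPlantedCounts:
    def test_fractions_straddle_thresholds(self):
        slides = sample_planted_counts(n_per_class=30, seed=7)
        thr = ThresholdConfig()
        for counts, label in slides:
            assert hierarchical_classify(counts, thr) == label

    def test_counts_scale(self):
        slides = sample_planted_counts(n_per_class=10, seed=8)
        assert len(slides) == 40


class TestAnnotatorPanel:
    @pytest.fixture
    def truth(self):
        rng = np.random.default_rng(10)
        return pd.DataFrame({
            "slide_id": [f"s{i:04d}" for i in range(2000)],
            "label": rng.choice(SLIDE_CLASSES, 2000),
        })

    def test_identity_model_reproduces_truth(self, truth):
        panel = simulate_annotator_panel(truth.head(50), AnnotatorModel.identity(),
                                         seed=0)
        wide = panel.pivot(index="slide_id", columns="annotator_id", values="label")
        merged = wide.join(truth.set_index("slide_id"))
        for col in wide.columns:
            assert (merged[col] == merged["label"]).all()
        assert mean_pairwise_kappa(panel).mean == 1.0

    def test_uniform_confusion_gives_chance_kappa(self, truth):
        m = AnnotatorModel.symmetric(0.25)  # uniform rows
        panel = simulate_annotator_panel(truth, m, seed=1)
        assert abs(mean_pairwise_kappa(panel).mean) < 0.05

    def test_empirical_accuracy_matches_diagonal(self, truth):
        m = AnnotatorModel.symmetric(0.9)
        panel = simulate_annotator_panel(truth, m, seed=2)
        merged = panel.merge(truth, on="slide_id", suffixes=("", "_true"))
        for aid, grp in merged.groupby("annotator_id"):
            acc = (grp["label"] == grp["label_true"]).mean()
            assert abs(acc - 0.9) < 0.02

    def test_simulated_kappa_matches_analytic(self, truth):
        m = AnnotatorModel.symmetric(0.8)
        panel = simulate_annotator_panel(truth, m, seed=3)
        expected = expected_pairwise_kappa(m)
        assert abs(mean_pairwise_kappa(panel).mean - expected) < 0.04

    def test_nonstochastic_rows_rejected(self):
        bad = np.eye(4) * 0.9
        with pytest.raises(ValueError, match="stochastic"):
            AnnotatorModel(confusion=(bad,))
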