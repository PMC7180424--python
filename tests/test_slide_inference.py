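import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polypscope.slide_inference import (
    ClassCounts,
    GridSpec,
    NoLesionError,
    ThresholdConfig,
    calibrate_thresholds,
    count_patch_classes,
    hierarchical_classify,
    infer_slide,
)
from polypscope.synthetic import (
    DEFAULT_TEXTURES,
    SlideSpec,
    generate_slide,
    render_texture,
    sample_planted_counts,
)
from polypscope.wsi_io import PatchPrediction

PAPER_THR = ThresholdConfig()  # villous > 0.30, ssa > 0.015


def _onehot(cls_idx):
    v = np.zeros(5)
    v[cls_idx] = 1.0
    return v


class TestCountPatchClasses:
    def test_argmax_tally(self):
        preds = [PatchPrediction("s", 0, 0, 224, _onehot(i)) for i in (0, 0, 2)]
        counts = count_patch_classes(preds)
        assert (counts.n_TA, counts.n_TVA, counts.n_HP, counts.n_SSA,
                counts.n_NORM) == (2, 0, 1, 0, 0)

    def test_empty_list_gives_zero_counts(self):
        assert count_patch_classes([]).total == 0

    def test_mixed_slides_rejected(self):
        preds = [PatchPrediction("a", 0, 0, 224, _onehot(0)),
                 PatchPrediction("b", 0, 0, 224, _onehot(0))]
        with pytest.raises(ValueError, match="multiple slides"):
            count_patch_classes(preds)

    def test_counts_equal_planted_histogram(self):
        """Oracle one-hot predictions from a generated slide reproduce the
        planted tile-label histogram."""
        slide = generate_slide(SlideSpec("TVA", villous_fraction=0.4), seed=12)
        preds = [
            PatchPrediction(slide.slide_id, x, y, 224,
                            _onehot(["TA", "TVA", "HP", "SSA", "NORM"].index(lab)))
            for x, y, lab in slide.oracle_patch_labels()
        ]
        counts = count_patch_classes(preds)
        tiles = list(slide.tile_labels.values())
        assert counts.n_TA == tiles.count("TA")
        assert counts.n_TVA == tiles.count("TVA")


class TestHierarchicalRule:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((60, 10, 5, 0, 200), "TA"),     # 10/70 ~ 0.143 <= 0.30
            ((50, 50, 0, 0, 0), "TVA"),      # 0.50 > 0.30
            ((0, 0, 197, 3, 0), "HP"),       # 0.015, strict > fails
            ((0, 0, 196, 4, 0), "SSA"),      # 0.02 > 0.015
            ((70, 30, 0, 0, 10), "TA"),      # 0.30 not > 0.30, boundary
        ],
    )
    def test_rule_with_default_thresholds(self, counts, expected):
        assert hierarchical_classify(ClassCounts("s", *counts), PAPER_THR) == expected

    def test_no_lesion_error(self):
        with pytest.raises(NoLesionError, match="no lesion"):
            hierarchical_classify(ClassCounts("s", 0, 0, 0, 0, 81), PAPER_THR)

    def test_branch_tie_goes_adenomatous(self):
        assert hierarchical_classify(ClassCounts("s", 5, 0, 5, 0, 0), PAPER_THR) == "TA"

    def test_all_polyp_denominator_mode(self):
        thr = ThresholdConfig(denominator="all_polyp")
        # 40 TVA / 100 polyp = 0.40 > 0.30 -> TVA even with serrated dilution
        counts = ClassCounts("s", 35, 40, 25, 0, 0)
        assert hierarchical_classify(counts, thr) == "TVA"

    @settings(max_examples=300, deadline=None)
    @given(
        n_ta=st.integers(0, 500), n_tva=st.integers(0, 500),
        n_hp=st.integers(0, 500), n_ssa=st.integers(0, 500),
        t_lo=st.floats(0, 1), t_hi=st.floats(0, 1),
    )
    def test_threshold_monotonicity(self, n_ta, n_tva, n_hp, n_ssa, t_lo, t_hi):
        """Raising the villous threshold can only move TVA -> TA; raising the
        SSA threshold can only move SSA -> HP."""
        if n_ta + n_tva + n_hp + n_ssa == 0:
            return
        lo, hi = sorted((t_lo, t_hi))
        counts = ClassCounts("s", n_ta, n_tva, n_hp, n_ssa, 0)
        d_lo = hierarchical_classify(counts, ThresholdConfig(lo, 0.5))
        d_hi = hierarchical_classify(counts, ThresholdConfig(hi, 0.5))
        assert (d_lo, d_hi) != ("TA", "TVA")
        d_lo = hierarchical_classify(counts, ThresholdConfig(0.5, lo))
        d_hi = hierarchical_classify(counts, ThresholdConfig(0.5, hi))
        assert (d_lo, d_hi) != ("HP", "SSA")

    def test_purity(self):
        c = ClassCounts("s", 10, 5, 2, 1, 40)
        assert hierarchical_classify(c, PAPER_THR) == hierarchical_classify(c, PAPER_THR)


class TestCalibration:
    def test_planted_threshold_recovery(self):
        """Grid search over count-level planted cohorts recovers the planted
        thresholds within one grid step."""
        slides = sample_planted_counts(n_per_class=50, seed=13)
        cal = calibrate_thresholds(slides, GridSpec())
        assert abs(cal.thresholds.villous_threshold - 0.30) <= 0.05
        assert abs(cal.thresholds.ssa_threshold - 0.015) <= 0.005
        assert cal.surface.max() == 1.0

    def test_single_point_grid(self):
        slides = sample_planted_counts(n_per_class=5, seed=14)
        grid = GridSpec(villous_grid=(0.3,), ssa_grid=(0.015,))
        cal = calibrate_thresholds(slides, grid)
        assert cal.thresholds.villous_threshold == 0.3
        assert cal.surface.shape == (1, 1)

    def test_tie_broken_toward_smallest(self):
        # trivially separable: every grid point in a wide band is optimal
        slides = [
            (ClassCounts("a", 100, 0, 0, 0, 0), "TA"),
            (ClassCounts("b", 0, 100, 0, 0, 0), "TVA"),
            (ClassCounts("c", 0, 0, 100, 0, 0), "HP"),
            (ClassCounts("d", 0, 0, 0, 100, 0), "SSA"),
        ]
        cal = calibrate_thresholds(slides, GridSpec())
        assert cal.thresholds.villous_threshold == 0.0
        assert cal.thresholds.ssa_threshold == 0.0

    def test_one_branch_only_rejected(self):
        slides = [(ClassCounts("a", 100, 0, 0, 0, 0), "TA")]
        with pytest.raises(ValueError, match="branch"):
            calibrate_thresholds(slides, GridSpec())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            GridSpec(villous_grid=())


@pytest.fixture
def patch_spec():
    from polypscope.patching import PatchSpec

    return PatchSpec(extraction_downsample=1)


class TestInferSlide:
    def test_ta_slide_diagnosed_ta(self, trained_model, patch_spec):
        slide = generate_slide(SlideSpec("TA", villous_fraction=0.1), seed=15)
        diagnosis, preds = infer_slide(
            trained_model["model"], slide.image, patch_spec, PAPER_THR, "s")
        assert diagnosis == "TA"
        assert len(preds) == 81

    def test_ssa_slide_diagnosed_ssa(self, trained_model, patch_spec):
        slide = generate_slide(SlideSpec("SSA", ssa_fraction=0.3), seed=16)
        diagnosis, _ = infer_slide(
            trained_model["model"], slide.image, patch_spec, PAPER_THR, "s")
        assert diagnosis == "SSA"

    def test_all_norm_slide_raises_no_lesion(self, trained_model, patch_spec):
        rng = np.random.default_rng(17)
        image = render_texture(DEFAULT_TEXTURES["NORM"], 1120, 1120, rng)
        with pytest.raises(NoLesionError):
            infer_slide(trained_model["model"], image, patch_spec, PAPER_THR, "s")
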