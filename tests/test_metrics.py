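"""Overlap metrics, agreement statistics and the reference loss formulas."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import shoulderx as sx
from shoulderx.metrics import box_iou


def random_mask_pair(rng, shape=(16, 16)):
    a = rng.random(shape) < rng.uniform(0.1, 0.9)
    b = rng.random(shape) < rng.uniform(0.1, 0.9)
    if not a.any() and not b.any():
        a[0, 0] = True
    return a, b


class TestOverlapMetrics:
    def test_counting_example(self):
        a = np.zeros((3, 3), dtype=bool)
        b = np.zeros((3, 3), dtype=bool)
        a[0, :3] = True  # |A| = 3
        b[0, 1:] = True
        b[1, 0] = True  # |B| = 3, |A n B| = 2
        assert sx.dsc(a, b) == pytest.approx(2 * 2 / 6)
        assert sx.jaccard(a, b) == pytest.approx(2 / 4)

    def test_identity_and_disjoint(self):
        a = np.eye(5, dtype=bool)
        assert sx.dsc(a, a) == 1.0 and sx.jaccard(a, a) == 1.0
        b = np.zeros((5, 5), dtype=bool)
        b[0, 1] = True
        assert sx.dsc(a, b) == 0.0 and sx.jaccard(a, b) == 0.0

    def test_both_empty_undefined(self):
        empty = np.zeros((4, 4), dtype=bool)
        with pytest.raises(sx.UndefinedMetricError):
            sx.dsc(empty, empty)
        with pytest.raises(sx.UndefinedMetricError):
            sx.jaccard(empty, empty)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sx.dsc(np.ones((2, 2), dtype=bool), np.ones((3, 3), dtype=bool))

    @pytest.mark.parametrize("seed", range(10))
    def test_dice_jaccard_identity(self, seed):
        """DSC = 2J/(1+J), DSC >= J, and both are symmetric."""
        rng = np.random.default_rng(seed)
        a, b = random_mask_pair(rng)
        d, j = sx.dsc(a, b), sx.jaccard(a, b)
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
        assert d >= j
        assert sx.dsc(b, a) == d and sx.jaccard(b, a) == j


class TestICC:
    def test_hand_computed_table(self):
        """3x2 table [[1,2],[3,4],[5,6]]: MSB = 8, MSW = 0.5 by hand ANOVA."""
        assert sx.icc_one_way(np.array([[1, 2], [3, 4], [5, 6]])) == pytest.approx(
            7.5 / 8.5, abs=1e-12
        )

    def test_identical_columns_give_one(self):
        x = np.array([[1.0, 1.0], [4.0, 4.0], [9.0, 9.0]])
        assert sx.icc_one_way(x) == 1.0

    def test_equal_subject_means_nonpositive(self):
        x = np.array([[1.0, 3.0], [3.0, 1.0], [0.0, 4.0]])
        assert sx.icc_one_way(x) <= 0

    def test_all_identical_undefined(self):
        with pytest.raises(sx.UndefinedMetricError):
            sx.icc_one_way(np.full((4, 3), 2.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_invariances(self, seed):
        """Permuting subjects, or ratings within a subject, leaves ICC(1,1) unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.normal(50, 5, (10, 1)) + rng.normal(0, 1, (10, 3))
        base = sx.icc_one_way(x)
        assert sx.icc_one_way(x[rng.permutation(10)]) == pytest.approx(base, abs=1e-12)
        shuffled = x.copy()
        for row in shuffled:
            rng.shuffle(row)
        assert sx.icc_one_way(shuffled) == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pingouin_oracle(self, seed):
        """Independent cross-check of the one-way ANOVA route."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        n, k = 15, 3
        x = rng.normal(40, 6, (n, 1)) + rng.normal(0, 2, (n, k))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "value": x.ravel(),
            }
        )
        res = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="value")
        row = res[res["Type"] == "ICC(1,1)"].iloc[0] if (res["Type"] == "ICC(1,1)").any() \
            else res[res["Type"] == "ICC1"].iloc[0]
        assert sx.icc_one_way(x) == pytest.approx(row["ICC"], abs=1e-9)
        lo, hi = sx.icc_confidence_interval(x)
        assert lo == pytest.approx(row["CI95"][0], abs=0.005)
        assert hi == pytest.approx(row["CI95"][1], abs=0.005)


class TestICCConfidenceInterval:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(3)
        return rng.normal(30, 4, (12, 1)) + rng.normal(0, 1.5, (12, 3))

    def test_contains_point_estimate(self, table):
        lo, hi = sx.icc_confidence_interval(table)
        assert lo <= sx.icc_one_way(table) <= hi

    def test_wider_for_smaller_n(self):
        rng = np.random.default_rng(9)
        subj = rng.normal(0, 2, (50, 1))
        noise = rng.normal(0, 1, (50, 3))
        big = subj + noise
        small = big[:5]
        lo_b, hi_b = sx.icc_confidence_interval(big)
        lo_s, hi_s = sx.icc_confidence_interval(small)
        assert (hi_s - lo_s) > (hi_b - lo_b)

    def test_levels_nest(self, table):
        lo95, hi95 = sx.icc_confidence_interval(table, level=0.95)
        lo99, hi99 = sx.icc_confidence_interval(table, level=0.99)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_zero_within_variance_degenerates_to_one(self):
        x = np.array([[1.0, 1.0], [4.0, 4.0], [9.0, 9.0]])
        assert sx.icc_confidence_interval(x) == (1.0, 1.0)


class TestInterpretICC:
    @pytest.mark.parametrize(
        "value, label",
        [
            (0.92, "excellent"),
            (0.9, "excellent"),
            (0.89, "good"),
            (0.80, "good"),
            (0.75, "good"),
            (0.60, "moderate"),
            (0.5, "moderate"),
            (0.499, "poor"),
            (0.30, "poor"),
            (-0.2, "poor"),
        ],
    )
    def test_bands(self, value, label):
        assert sx.interpret_icc(value) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            sx.interpret_icc(1.01)


class TestPearson:
    def test_perfect_affine(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        assert sx.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert sx.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert sx.pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_constant_sequence_undefined(self):
        with pytest.raises(sx.UndefinedMetricError):
            sx.pearson_r([1, 1, 1], [1, 2, 3])

    @given(
        a=st.floats(0.01, 50),
        b=st.floats(-100, 100),
    )
    def test_positive_affine_invariance(self, a, b):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5])
        base = sx.pearson_r(x, y)
        assert sx.pearson_r(a * x + b, y) == pytest.approx(base, abs=1e-7)


class TestRMSE:
    def test_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert sx.rmse(x, x) == 0.0
        assert sx.rmse(x, x + 2.5) == pytest.approx(2.5)
        assert sx.rmse(np.array([0, 0, 0.0]), np.array([-2, 1, -3.0])) == pytest.approx(
            math.sqrt(14 / 3), abs=1e-12
        )

    def test_symmetric_and_bounds_mean_residual(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert sx.rmse(x, y) == sx.rmse(y, x)
        assert sx.rmse(x, y) >= abs(np.mean(x - y))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sx.rmse([], [])


class TestBCELoss:
    def test_examples(self):
        assert sx.bce_loss(1.0, 1) <= 1e-6
        assert sx.bce_loss(0.5, 1) == pytest.approx(math.log(2), abs=1e-12)
        # clamping keeps the perfect-confidence mistake finite at -ln(1e-7)
        assert sx.bce_loss(0.0, 1) == pytest.approx(-math.log(1e-7), abs=1e-6)

    def test_weight_scales_linearly(self):
        assert sx.bce_loss(0.3, 0, weight=2.5) == pytest.approx(2.5 * sx.bce_loss(0.3, 0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sx.bce_loss(0.5, 2)
        with pytest.raises(ValueError):
            sx.bce_loss(0.5, 1, weight=0)


class TestCIoULoss:
    def test_identical_boxes_zero(self):
        b = sx.Box(3, 4, 2, 5)
        assert sx.ciou_loss(b, b) == 0.0

    def test_disjoint_example(self):
        """IoU = 0, rho^2 = 16, c^2 = 40, v = 0: loss = 1 + 16/40 = 1.4."""
        assert sx.ciou_loss(sx.Box(0, 0, 2, 2), sx.Box(4, 0, 2, 2)) == pytest.approx(
            1.4, abs=1e-12
        )

    def test_aspect_ratio_example(self):
        """Concentric 2x2 vs 4x1 boxes, checked against a direct numeric oracle."""
        pred, truth = sx.Box(0, 0, 2, 2), sx.Box(0, 0, 4, 1)
        iou = 2.0 / 6.0  # overlap 2x1 over union 4+4-2
        v = (4 / math.pi**2) * (math.atan(4.0) - math.atan(1.0)) ** 2
        alpha = v / ((1 - iou) + v)
        expected = 1 - iou + 0.0 + alpha * v
        got = sx.ciou_loss(pred, truth)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.6845, abs=1e-4)

    @pytest.mark.parametrize("seed", range(8))
    def test_lower_bounded_by_iou_term(self, seed):
        rng = np.random.default_rng(seed)
        boxes = [sx.Box(*rng.uniform(1, 10, 2), *rng.uniform(0.5, 8, 2)) for _ in range(2)]
        assert sx.ciou_loss(*boxes) >= 1 - box_iou(*boxes) - 1e-12

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            sx.Box(0, 0, 0, 2)


class TestSummaries:
    def test_summary_stats(self):
        assert sx.summary_stats([1, 2, 3]) == pytest.approx((2.0, 1.0, 1.0, 3.0))
        assert sx.summary_stats([4.0, 4.0, 4.0])[1] == 0.0
        with pytest.raises(ValueError):
            sx.summary_stats([1.0])

    def test_band_distribution_partitions(self, reference_phantom):
        _, masks = reference_phantom
        rec = sx.measure_study(masks, source_id="a")
        counts = sx.band_distribution([rec, rec, rec])
        for measure, bands in counts.items():
            assert sum(bands.values()) == 3

    def test_band_distribution_spreads_values(self, base_landmarks):
        lm = base_landmarks
        recs = [
            sx.MeasurementRecord(source_id=str(v), csa=v, ai=0.8, laa=50.0, landmarks=lm)
            for v in (28.0, 31.0, 36.0)
        ]
        counts = sx.band_distribution(recs)
        assert list(counts["CSA"].values()) == [1, 1, 1]
        assert counts["AI"]["0.7 ≤ AI < 1"] == 3

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            sx.band_distribution([])
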