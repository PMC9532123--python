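import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chi2_contingency

from helicalct import (
    BinaryMask,
    ConfusionCounts,
    ValidationError,
    VoxelVolume,
    chi_square_2x2,
    confusion_from_labels,
    diagnostic_report,
    dice,
    threshold_segment,
)


def mask(arr):
    a = np.asarray(arr, dtype=bool)
    return BinaryMask(a, (1.0,) * a.ndim, (0.0,) * a.ndim)


class TestDice:
    def test_disjoint_masks_give_zero(self):
        m = np.zeros((10, 10), dtype=bool); m[:5] = True
        n = np.zeros((10, 10), dtype=bool); n[5:] = True
        assert dice(mask(m), mask(n)) == 0.0

    def test_identical_masks_give_one(self):
        m = np.zeros((10, 10), dtype=bool); m[2:7, 3:8] = True
        assert dice(mask(m), mask(m.copy())) == 1.0

    def test_counted_overlap(self):
        m = np.zeros(200, dtype=bool); m[:100] = True
        n = np.zeros(200, dtype=bool); n[75:125] = True
        assert dice(m, n) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((4, 4), dtype=bool)
        assert dice(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice(np.zeros((3, 3), dtype=bool), np.zeros((4, 4), dtype=bool))

    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_symmetric_bounded_and_exact_iff_identical(self, a_bits, b_bits):
        a = np.array([(a_bits >> k) & 1 for k in range(20)], dtype=bool)
        b = np.array([(b_bits >> k) & 1 for k in range(20)], dtype=bool)
        d1, d2 = dice(a, b), dice(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0
        if a.any() or b.any():
            assert (d1 == 1.0) == bool(np.array_equal(a, b))


class TestThresholdSegment:
    def test_extreme_thresholds(self):
        vol = VoxelVolume(np.random.default_rng(0).uniform(0, 1, (5, 5, 5)),
                          (1, 1, 1), (0, 0, 0))
        assert threshold_segment(vol, -1.0).values.all()
        assert not threshold_segment(vol, 2.0).values.any()

    def test_half_max_recovers_disk_area(self, disk_phantom):
        from helicalct.projector import simulate_planar_fan
        from helicalct import fan_fbp
        from conftest import make_geom

        g = make_geom(n_gamma=181, fan_half=0.4, pitch=10.0)
        fan = simulate_planar_fan(disk_phantom, g, 0.0, n_beta=240, beta_R=0.0)
        img = fan_fbp(fan, (192, 192), (0.75, 0.75))
        seg = threshold_segment(img.values, 0.01)  # half of mu = 0.02
        area = seg.values.sum() * 0.75**2
        assert area == pytest.approx(np.pi * 40**2, rel=0.03)


class TestConfusionAndReport:
    def test_confusion_against_loop_oracle(self):
        rng = np.random.default_rng(1)
        t = rng.random(200) < 0.4
        p = rng.random(200) < 0.5
        c = confusion_from_labels(t, p)
        tp = sum(1 for a, b in zip(t, p) if a and b)
        fp = sum(1 for a, b in zip(t, p) if not a and b)
        tn = sum(1 for a, b in zip(t, p) if not a and not b)
        fn = sum(1 for a, b in zip(t, p) if a and not b)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_degenerate_label_vectors(self):
        c = confusion_from_labels([True] * 5, [True] * 5)
        assert (c.fp, c.fn, c.tn) == (0, 0, 0)
        c = confusion_from_labels([True] * 5, [False] * 5)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 0, 5)

    def test_perfect_classifier(self):
        rep = diagnostic_report(ConfusionCounts(tp=30, fp=0, tn=20, fn=0))
        assert rep.sensitivity == rep.specificity == rep.ppv == rep.npv == 1.0
        assert rep.coincidence_rate == 1.0
        assert rep.missed_rate == 0.0 and rep.misdiagnosis_rate == 0.0

    def test_hand_arithmetic(self):
        rep = diagnostic_report(ConfusionCounts(tp=48, fn=2, tn=40, fp=10))
        assert rep.sensitivity == pytest.approx(48 / 50)
        assert rep.specificity == pytest.approx(40 / 50)
        assert rep.ppv == pytest.approx(48 / 58)
        assert rep.npv == pytest.approx(40 / 42)
        assert rep.coincidence_rate == pytest.approx(88 / 100)
        # as-printed denominators: (tn + fp)
        assert rep.missed_rate == pytest.approx(2 / 50)
        assert rep.misdiagnosis_rate == pytest.approx(10 / 50)

    def test_conventional_flag_adds_textbook_rates(self):
        rep = diagnostic_report(ConfusionCounts(tp=48, fn=2, tn=40, fp=10), conventional=True)
        assert rep.conventional_missed_rate == pytest.approx(2 / 50)
        assert rep.conventional_misdiagnosis_rate == pytest.approx(10 / 50)
        # they differ from the as-printed ones when tn+fp != fn+tp / fp+tn
        rep2 = diagnostic_report(ConfusionCounts(tp=10, fn=2, tn=40, fp=10), conventional=True)
        assert rep2.missed_rate != rep2.conventional_missed_rate

    def test_symmetric_counts_give_ppv_equal_npv(self):
        rep = diagnostic_report(ConfusionCounts(tp=25, tn=25, fp=7, fn=7))
        assert rep.ppv == rep.npv

    def test_zero_denominators_flagged_not_nan(self):
        rep = diagnostic_report(ConfusionCounts(tp=10, fp=0, tn=0, fn=0))
        assert rep.specificity is None
        assert "specificity" in rep.undefined
        with pytest.raises(ValidationError):
            diagnostic_report(ConfusionCounts(0, 0, 0, 0))

    def test_entries_are_proportions(self):
        """All standard rates lie in [0,1]; the as-printed missed rate
        (denominator tn+fp) is only non-negative — it exceeds 1 when
        fn > tn + fp, which the formula sheet's own data never exhibits."""
        rng = np.random.default_rng(4)
        bounded = ("detection_rate", "sensitivity", "specificity", "ppv",
                   "npv", "coincidence_rate", "misdiagnosis_rate")
        for _ in range(100):
            c = ConfusionCounts(*[int(v) for v in rng.integers(1, 60, 4)])
            rep = diagnostic_report(c, conventional=True)
            d = rep.to_dict()
            for name in bounded:
                assert 0.0 <= d[name] <= 1.0
            assert rep.missed_rate >= 0.0
            assert 0.0 <= rep.conventional_missed_rate <= 1.0
            assert rep.coincidence_rate == (c.tp + c.tn) / c.total


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)
        stat, _ = chi_square_2x2([[30, 15], [60, 30]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_textbook_oe_formula(self):
        table = np.array([[30, 10], [10, 30]])
        row, col, n = table.sum(1), table.sum(0), table.sum()
        expected = np.outer(row, col) / n
        by_hand = float(((table - expected) ** 2 / expected).sum())
        stat, p = chi_square_2x2(table)
        assert stat == pytest.approx(by_hand)
        ref_stat, ref_p, _, _ = chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p)

    def test_invariant_under_row_and_column_swap(self):
        t = [[12, 7], [3, 20]]
        s0, _ = chi_square_2x2(t)
        s1, _ = chi_square_2x2([t[1], t[0]])
        s2, _ = chi_square_2x2([[12, 3], [7, 20]][::-1])
        assert s0 == pytest.approx(s1)
        s3, _ = chi_square_2x2([[r[1], r[0]] for r in t])
        assert s0 == pytest.approx(s3)

    def test_continuity_correction_reduces_statistic(self):
        s_plain, _ = chi_square_2x2([[12, 7], [3, 20]])
        s_corr, _ = chi_square_2x2([[12, 7], [3, 20]], correction=True)
        assert s_corr < s_plain
        ref = chi2_contingency(np.array([[12, 7], [3, 20]]), correction=True)
        assert s_corr == pytest.approx(ref[0])

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2([[0, 0], [5, 5]])
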