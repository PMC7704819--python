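"""Dice, volume/FF agreement, ICC and Welch t statistics."""

import numpy as np
import pytest
from scipy import stats

from muscleseg import (
    FatWaterVolume,
    MuscleLabelVolume,
    dice,
    evaluate_testset,
    icc_meanff,
    percent_volume_diff,
    welch_t_one_tailed,
)


def _lab(arr):
    return MuscleLabelVolume(np.asarray(arr, np.int16), (1, 1, 1))


class TestDice:
    def test_identity_is_one(self, rng):
        a = _lab(rng.integers(0, 5, (6, 6, 3)))
        for roi in (1, 2, 3, 4):
            assert dice(a, a, roi) == 1.0

    def test_disjoint_nonempty_is_zero(self):
        a = np.zeros((4, 4, 2), np.int16)
        b = np.zeros((4, 4, 2), np.int16)
        a[0, 0, 0] = 1
        b[3, 3, 1] = 1
        assert dice(_lab(a), _lab(b), 1) == 0.0

    def test_counting_oracle_six_four_overlap_three(self):
        a = np.zeros((4, 4, 2), np.int16)
        b = np.zeros((4, 4, 2), np.int16)
        a.flat[:6] = 1
        b.flat[3:7] = 1  # overlap voxels 3,4,5 -> 3
        assert dice(_lab(a), _lab(b), 1) == pytest.approx(2 * 3 / (6 + 4))

    def test_symmetry_on_random_masks(self, rng):
        for _ in range(10):
            a = _lab(rng.integers(0, 3, (5, 5, 3)))
            b = _lab(rng.integers(0, 3, (5, 5, 3)))
            assert dice(a, b, 2) == dice(b, a, 2)

    def test_both_empty_is_vacuously_perfect(self):
        z = _lab(np.zeros((3, 3, 1)))
        assert dice(z, z, 4) == 1.0

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(_lab(np.zeros((3, 3, 1))), _lab(np.zeros((3, 3, 2))), 1)


def test_percent_volume_diff_examples():
    assert percent_volume_diff(100.0, 100.0) == 0.0
    assert percent_volume_diff(100.0, 110.0) == pytest.approx(10.0)
    assert percent_volume_diff(200.0, 150.0) == pytest.approx(-25.0)
    with pytest.warns(UserWarning):
        assert np.isnan(percent_volume_diff(0.0, 10.0))


def icc2_oracle(x):
    """Independent ICC(2,1) from explicit ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ssr = k * sum((x[i].mean() - grand) ** 2 for i in range(n))
    ssc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(3, 9)), int(rng.integers(2, 5))
            x = rng.normal(10, 3, (n, k))
            res = icc_meanff(x)
            assert res.icc_estimate == pytest.approx(icc2_oracle(x), abs=1e-10)
            assert res.ci95_low <= res.icc_estimate <= res.ci95_high

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.normal(20, 5, (8, 3))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "rater": np.tile(np.arange(3), 8),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = ref.loc["ICC(A,1)"]  # two-way random, absolute agreement, single
        res = icc_meanff(x, model="icc2")
        assert res.icc_estimate == pytest.approx(row["ICC"], abs=1e-8)
        assert res.ci95_low == pytest.approx(row["CI95"][0], abs=0.01)
        assert res.ci95_high == pytest.approx(row["CI95"][1], abs=0.01)
        res3 = icc_meanff(x, model="icc3")
        assert res3.icc_estimate == pytest.approx(ref.loc["ICC(C,1)"]["ICC"], abs=1e-8)

    def test_perfect_repeatability_returns_one(self):
        col = np.array([1.0, 5.0, 9.0, 13.0])
        x = np.column_stack([col, col, col])
        res = icc_meanff(x)
        assert res.icc_estimate == 1.0 and not res.degenerate

    def test_all_equal_table_is_degenerate(self):
        res = icc_meanff(np.full((4, 3), 2.5))
        assert res.degenerate and np.isnan(res.icc_estimate)

    def test_shift_invariance_and_upper_bound(self, rng):
        x = rng.normal(0, 1, (6, 3))
        a = icc_meanff(x)
        b = icc_meanff(x + 100.0)
        assert a.icc_estimate == pytest.approx(b.icc_estimate, abs=1e-9)
        assert a.icc_estimate <= 1.0

    def test_incomplete_table_rejected(self):
        x = np.ones((3, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            icc_meanff(x)


def welch_oracle(a, b, direction):
    """Reference Welch statistic, Welch-Satterthwaite df and one-tailed p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df)
    return t, df, p


class TestWelch:
    def test_matches_reference_formulas(self, rng):
        for _ in range(10):
            a = rng.normal(10, 2, int(rng.integers(4, 12)))
            b = rng.normal(11, 4, int(rng.integers(4, 12)))
            res = welch_t_one_tailed(a, b, "greater")
            t, df, p = welch_oracle(a, b, "greater")
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.df == pytest.approx(df, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_identical_groups_give_half(self):
        g = [1.0, 2.0, 3.0]
        assert welch_t_one_tailed(g, list(g)).p == pytest.approx(0.5)

    def test_p_decreases_monotonically_with_shift(self, rng):
        base = rng.normal(0, 1, 8)
        other = rng.normal(0, 1, 8)
        ps = [welch_t_one_tailed(base + s, other, "greater").p for s in (0.0, 1.0, 2.0, 4.0)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_swapped_groups_with_reversed_direction_agree(self, rng):
        a = rng.normal(5, 1, 6)
        b = rng.normal(6, 2, 7)
        assert welch_t_one_tailed(a, b, "greater").p == pytest.approx(
            welch_t_one_tailed(b, a, "less").p, abs=1e-12
        )

    def test_degenerate_zero_variance_flagged(self):
        res = welch_t_one_tailed([2.0, 2.0], [2.0, 2.0])
        assert res.flagged and np.isnan(res.p)


def _pair(manual, auto, shape=(6, 6, 3)):
    water = np.full(shape, 8.0)
    fat = np.full(shape, 2.0)
    vol = FatWaterVolume(water, fat, (1, 1, 1))
    return _lab(manual), _lab(auto), vol


class TestEvaluateTestset:
    def _masks(self):
        manual = np.zeros((6, 6, 3), np.int16)
        manual[1:5, 1:5, :] = 1
        auto = np.zeros((6, 6, 3), np.int16)
        auto[2:4, 2:4, :] = 1  # eroded variant
        return manual, auto

    def test_identical_repeats_average_to_single_row(self):
        manual, auto = self._masks()
        m, a, v = _pair(manual, auto)
        rep = evaluate_testset([(m, a, v, "T1", r) for r in range(3)])
        single = evaluate_testset([(m, a, v, "T1", 0)])
        for col in ("dice", "pct_volume_diff", "meanff_diff_pp"):
            assert np.allclose(rep.per_thigh[col], single.per_thigh[col], equal_nan=True)

    def test_perfect_agreement(self):
        manual, _ = self._masks()
        m, a, v = _pair(manual, manual.copy())
        rep = evaluate_testset([(m, a, v, "T1", 0)])
        assert rep.summary["mean_dice"] == 1.0
        assert rep.summary["mean_abs_pct_volume_diff"] == 0.0
        assert rep.summary["mean_abs_meanff_diff_pp"] == 0.0

    def test_eroded_masks_match_hand_computed_values(self):
        manual, auto = self._masks()
        m, a, v = _pair(manual, auto)
        rep = evaluate_testset([(m, a, v, "T1", 0)])
        row = rep.per_scan[rep.per_scan["roi"] == 1].iloc[0]
        # manual 4x4x3=48 voxels, auto 2x2x3=12, overlap 12
        assert row["dice"] == pytest.approx(2 * 12 / (48 + 12))
        assert row["pct_volume_diff"] == pytest.approx((12 - 48) / 48 * 100)
        assert row["meanff_diff_pp"] == pytest.approx(0.0)  # uniform FF field

    def test_unequal_repeat_counts_weight_thighs_equally(self):
        manual, auto = self._masks()
        m, a, v = _pair(manual, auto)
        perfect = evaluate_testset(
            [(m, _lab(manual.copy()), v, "T1", 0)]
        ).per_thigh
        # thigh T1: two repeats (dice d), thigh T2: one perfect repeat
        rep = evaluate_testset(
            [
                (m, a, v, "T1", 0),
                (m, a, v, "T1", 1),
                (m, _lab(manual.copy()), v, "T2", 0),
            ]
        )
        d = dice(m, a, 1)
        roi1 = rep.per_thigh[rep.per_thigh["roi"] == 1].set_index("thigh_id")["dice"]
        assert roi1["T1"] == pytest.approx(d)
        assert roi1["T2"] == pytest.approx(1.0)
        # cohort mean over thighs, not scans
        per_roi_means = rep.per_thigh.groupby("roi")["dice"].mean()
        assert per_roi_means[1] == pytest.approx((d + 1.0) / 2)
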