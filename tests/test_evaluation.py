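"""Agreement statistics: Dice, volumes, ICC, Wilcoxon, terciles."""

import itertools

import numpy as np
import pytest

from mvseg.core import LabelMap
from mvseg.evaluation import (
    MaskPair,
    dice,
    evaluate_prediction,
    fold_table,
    icc_single_absolute,
    summarize,
    tercile_groups,
    volume_mL,
    wilcoxon_bonferroni,
)


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.random((8, 8, 8)) > 0.5
        m[0, 0, 0] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(16, bool)
        b = np.zeros(16, bool)
        a[:4], b[2:6] = True, True
        assert dice(a, b) == 0.5

    def test_matches_set_counting_oracle(self, rng):
        for _ in range(100):
            a = rng.random((5, 5, 5)) > rng.uniform(0.2, 0.8)
            b = rng.random((5, 5, 5)) > rng.uniform(0.2, 0.8)
            sa = set(map(tuple, np.argwhere(a)))
            sb = set(map(tuple, np.argwhere(b)))
            if not sa and not sb:
                assert dice(a, b) is None
                continue
            oracle = 2 * len(sa & sb) / (len(sa) + len(sb))
            got = dice(a, b)
            assert got == pytest.approx(oracle, abs=1e-12)
            assert got == dice(b, a)  # symmetry
            assert 0.0 <= got <= 1.0

    def test_both_empty_is_undefined(self):
        empty = np.zeros((3, 3, 3), bool)
        assert dice(empty, empty) is None

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))

    def test_mask_pair_container(self):
        a = np.zeros((10,), bool)
        a[:4] = True
        pair = MaskPair(A=a, B=a, voxel_volume_mm3=2.0)
        assert pair.dice() == 1.0
        assert pair.volumes_mL() == (0.008, 0.008)


class TestVolume:
    def test_empty_and_unit(self):
        assert volume_mL(np.zeros((5, 5), bool), 1.0) == 0.0
        assert volume_mL(np.ones(1000, bool), 1.0) == 1.0

    def test_voxel_volume_must_be_positive(self):
        with pytest.raises(ValueError):
            volume_mL(np.ones(3, bool), 0.0)


def _anova_icc_oracle(table):
    """Independent two-way ANOVA decomposition for ICC(A,1), k = 2."""
    x = np.asarray(table, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = (
        ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True)
          + grand) ** 2).sum() / ((n - 1) * (k - 1))
    )
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(1.0, 7.0)
        assert icc_single_absolute(np.stack([x, x], axis=1)) == pytest.approx(1.0)

    def test_matches_anova_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            table = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * 2
            assert icc_single_absolute(table) == pytest.approx(
                _anova_icc_oracle(table), abs=1e-9
            )

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        table = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1)) * 3
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 2),
                "rater": np.tile(["a", "b"], 8),
                "score": table.ravel(),
            }
        )
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        expected = float(res.loc[res["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc_single_absolute(table) == pytest.approx(expected, abs=1e-6)

    def test_constant_bias_lowers_absolute_agreement(self, rng):
        ref = rng.normal(size=10) * 3
        noisy = ref + rng.normal(size=10) * 0.1
        unbiased = icc_single_absolute(np.stack([ref, noisy], axis=1))
        biased = icc_single_absolute(np.stack([ref, noisy + 2.0], axis=1))
        assert biased < unbiased

    def test_no_between_subject_variance_is_undefined(self):
        assert icc_single_absolute([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]) is None

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_single_absolute([[1.0, 2.0]])


def _exact_wilcoxon_p(diffs):
    """Full 2^n sign-enumeration null for the two-sided signed-rank test."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= stat_obs:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_matches_exact_enumeration(self, rng):
        for _ in range(3):
            a = rng.normal(size=8)
            b = a + rng.normal(size=8) * 0.5
            res = wilcoxon_bonferroni(a, b, m=1)
            assert res.p_raw == pytest.approx(_exact_wilcoxon_p(a - b), abs=1e-10)

    def test_identical_samples_undefined(self):
        a = np.linspace(0, 1, 8)
        assert wilcoxon_bonferroni(a, a) is None

    def test_bonferroni_cap(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(size=12) * 2
        res = wilcoxon_bonferroni(a, b, m=6)
        assert res.p_corrected == min(1.0, 6 * res.p_raw)
        assert res.p_corrected <= 1.0

    def test_too_few_nonzero_differences_rejected(self):
        a = np.zeros(8)
        b = np.zeros(8)
        b[0] = 1.0
        with pytest.raises(ValueError):
            wilcoxon_bonferroni(a, b)


class TestTerciles:
    def test_one_through_nine(self):
        groups = tercile_groups(np.arange(1.0, 10.0))
        assert list(groups) == ["small"] * 3 + ["medium"] * 3 + ["large"] * 3

    def test_29_distinct_volumes_split_10_9_10(self, rng):
        volumes = rng.permutation(rng.uniform(0.1, 3.0, size=29))
        groups = tercile_groups(volumes)
        counts = {g: int((groups == g).sum()) for g in ("small", "medium", "large")}
        assert counts == {"small": 10, "medium": 9, "large": 10}

    def test_all_equal_goes_to_one_group(self):
        groups = tercile_groups(np.full(7, 0.5))
        assert set(groups) == {"small"}

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            tercile_groups([1.0, 2.0])


def test_evaluate_prediction_and_summary_tables():
    data = np.zeros((10, 10, 10), np.uint8)
    data[2:8, 2:8, 2:8] = 2
    data[4:6, 4:6, 4:6] = 5
    ref = LabelMap(data, (1, 1, 1))
    pred = LabelMap(data.copy(), (1, 1, 1))
    pred.data[4, 4, 4] = 2  # one tumor voxel missed
    result = evaluate_prediction(ref, pred, subject="s0")
    assert result.metrics["vitreous"].dsc == pytest.approx(
        2 * 208 / (208 + 209)
    )
    assert result.metrics["tumor"].dsc == pytest.approx(2 * 7 / (8 + 7))
    assert result.metrics["lens"].dsc is None  # absent in both
    assert result.metrics["eye"].dsc == 1.0  # class union identical
    table = fold_table([result])
    assert set(table["class"]) == {
        "sclera", "vitreous", "lens", "retinal_detachment", "tumor", "eye"
    }
    row = table.set_index("class").loc["lens"]
    assert not row["dsc_defined"]
    summary = summarize([result])
    assert summary.loc["lens", "n_undefined_dsc"] == 1
    assert summary.loc["tumor", "dsc_median"] == pytest.approx(14 / 15)
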