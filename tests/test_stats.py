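"""Statistics contracts: hand-arithmetic oracles, algebraic identities
(F = t^2, GG bounds), and cross-checks against pingouin."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wplinet import (exclude_outliers, gg_epsilon, paired_t, rm_anova_3x2,
                     simple_effects)


def cell_table(values, subjects=None, a_levels=("a1", "a2"),
               b_levels=("b1", "b2")):
    """values[s][i][j] -> tidy table."""
    rows = []
    for s, per_subject in enumerate(values):
        for i, ai in enumerate(a_levels):
            for j, bj in enumerate(b_levels):
                rows.append({"subject": s, "channel_type": ai,
                             "music_type": bj,
                             "value": per_subject[i][j]})
    return pd.DataFrame(rows)


class TestOutlierScreen:
    def test_extreme_point_removed_hand_case(self):
        vals = list(range(1, 11)) + [1000]
        kept, log = exclude_outliers(vals, k=3.0)
        # hand check: mean 95.909, sd 300.86 -> only |1000 - mean| > 3 sd
        assert log["removed_values"] == [1000]
        assert sorted(kept) == list(range(1, 11))

    def test_identical_values_nothing_removed(self):
        kept, log = exclude_outliers([5.0] * 6, k=3.0)
        assert len(kept) == 6 and log["removed_indices"] == []

    def test_infinite_k_is_identity(self):
        vals = [1.0, 50.0, -200.0]
        kept, _ = exclude_outliers(vals, k=np.inf)
        assert kept.tolist() == vals

    def test_single_pass_not_iterative(self):
        # after removing the big outlier the next-largest would be an
        # outlier of the reduced sample; a single pass must keep it
        vals = [0.0] * 10 + [10.0, 1000.0]
        kept, log = exclude_outliers(vals, k=3.0)
        assert 10.0 in kept and log["removed_values"] == [1000.0]


class TestPairedT:
    def test_identical_pairs(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_case_sqrt3(self):
        """x=(1,2,3), y=(2,4,3): d=(-1,-2,0), t = -sqrt(3), df = 2."""
        res = paired_t([1.0, 2.0, 3.0], [2.0, 4.0, 3.0])
        assert res.statistic == pytest.approx(-np.sqrt(3.0), abs=1e-12)
        assert res.df == (2,)

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal((2, 10))
        fwd, rev = paired_t(x, y), paired_t(y, x)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p == pytest.approx(rev.p)

    def test_matches_one_sample_t_on_differences(self, rng):
        from scipy import stats as sps

        x, y = rng.standard_normal((2, 15))
        res = paired_t(x, y)
        t, p = sps.ttest_1samp(x - y, 0.0)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_degenerate_zero_variance_flagged(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.statistic == np.inf and res.p == 0.0
        assert res.extra["degenerate"] == "sd(d)=0"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_t([1.0], [2.0])


class TestGGEpsilon:
    def test_compound_symmetry_gives_one(self):
        cov = np.full((4, 4), 0.3)
        np.fill_diagonal(cov, 1.0)
        assert gg_epsilon(cov) == pytest.approx(1.0, abs=1e-12)

    def test_fixed_covariance_eigen_oracle(self):
        cov = np.array([[2.0, 0.5, 0.1],
                        [0.5, 1.0, 0.3],
                        [0.3, 0.3, 0.5]])
        cov[0, 2] = cov[2, 0] = 0.1
        cov[1, 2] = cov[2, 1] = 0.3
        # independent oracle: eigenvalues of the double-centered matrix
        k = 3
        H = np.eye(k) - 1 / k
        lam = np.linalg.eigvalsh(H @ cov @ H)
        lam = lam[lam > 1e-12]
        expected = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
        assert gg_epsilon(cov) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 6), st.integers(0, 2 ** 31 - 1))
    def test_bounds_hold_for_any_covariance(self, k, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((k, k + 2))
        cov = A @ A.T
        eps = gg_epsilon(cov)
        assert 1.0 / (k - 1) - 1e-9 <= eps <= 1.0 + 1e-9

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            gg_epsilon(np.zeros((3, 3)))

    def test_pingouin_cross_check(self, rng):
        import pingouin as pg

        data = rng.standard_normal((12, 4)) + rng.standard_normal((12, 1))
        eps = gg_epsilon(np.cov(data, rowvar=False))
        assert eps == pytest.approx(float(pg.epsilon(pd.DataFrame(data),
                                                     correction="gg")),
                                    abs=1e-9)


class TestRMAnova:
    def test_hand_worked_toy_table(self):
        """3 subjects, 2 x 2: SS and F frozen from an exact-fraction
        enumeration oracle (SS_A = 289/12, F_A = 289/7, F_B = 27, F_AB = 1)."""
        values = [
            [[1, 2], [3, 4]],
            [[2, 3], [5, 7]],
            [[1, 3], [4, 6]],
        ]
        res = rm_anova_3x2(cell_table(values))
        a = res.effects["channel_type"]
        b = res.effects["music_type"]
        ab = res.effects["channel_type:music_type"]
        assert a.extra["SS"] == pytest.approx(289 / 12, abs=1e-12)
        assert a.statistic == pytest.approx(289 / 7, abs=1e-9)
        assert b.statistic == pytest.approx(27.0, abs=1e-9)
        assert ab.statistic == pytest.approx(1.0, abs=1e-9)
        assert a.effect_size == pytest.approx(0.9537953795379538, abs=1e-12)
        assert b.effect_size == pytest.approx(0.9310344827586207, abs=1e-12)
        assert ab.effect_size == pytest.approx(1 / 3, abs=1e-12)

    def test_no_condition_variation_gives_zero_F(self, rng):
        base = rng.standard_normal(6)
        values = [[[v, v], [v, v]] for v in base]
        res = rm_anova_3x2(cell_table(values))
        for eff in res.effects.values():
            assert eff.statistic == 0.0
            assert eff.extra["SS"] == pytest.approx(0.0, abs=1e-18)

    def test_location_invariance(self, rng):
        vals = rng.standard_normal((8, 3, 2))
        t1 = cell_table(vals, a_levels=("a1", "a2", "a3"))
        vals2 = vals + 100.0
        t2 = cell_table(vals2, a_levels=("a1", "a2", "a3"))
        r1, r2 = rm_anova_3x2(t1), rm_anova_3x2(t2)
        for name in r1.effects:
            assert r1.effects[name].statistic == pytest.approx(
                r2.effects[name].statistic, rel=1e-9)
            assert r1.effects[name].p == pytest.approx(
                r2.effects[name].p, rel=1e-9)
            assert r1.effects[name].effect_size == pytest.approx(
                r2.effects[name].effect_size, rel=1e-9)

    def test_two_level_F_equals_paired_t_squared(self, rng):
        vals = rng.standard_normal((10, 3, 2))
        table = cell_table(vals, a_levels=("a1", "a2", "a3"))
        res = rm_anova_3x2(table)
        # collapse the 3-level factor, paired t on the 2-level one
        per_b = vals.mean(axis=1)
        t = paired_t(per_b[:, 0], per_b[:, 1])
        assert res.effects["music_type"].statistic == pytest.approx(
            t.statistic ** 2, abs=1e-9)
        assert res.effects["music_type"].extra["p_uncorrected"] == \
            pytest.approx(t.p, abs=1e-9)

    def test_gg_correction_never_lowers_p_when_F_exceeds_one(self, rng):
        """Deflating both df by epsilon <= 1 raises the p-value whenever
        F >= 1 (the correction is conservative in the significant regime;
        for F < 1 the direction can reverse, which is correct behavior)."""
        found = 0
        for trial in range(20):
            vals = (rng.standard_normal((9, 3, 2))
                    * np.array([1.0, 2.0, 0.5])[:, None])
            vals[:, 2, :] += 1.5  # strong level effect
            res = rm_anova_3x2(cell_table(vals, a_levels=("a1", "a2", "a3")))
            for eff in res.effects.values():
                assert eff.extra["epsilon"] <= 1.0 + 1e-12
                if eff.extra["p_uncorrected"] < 0.05:
                    found += 1
                    assert eff.p >= eff.extra["p_uncorrected"] - 1e-15
        assert found > 0

    def test_pingouin_cross_check(self, rng):
        import pingouin as pg

        vals = (rng.standard_normal((12, 3, 2))
                + rng.standard_normal((12, 1, 1)))
        table = cell_table(vals, a_levels=("a1", "a2", "a3"))
        mine = rm_anova_3x2(table)
        theirs = pg.rm_anova(data=table, dv="value",
                             within=["channel_type", "music_type"],
                             subject="subject", detailed=True)
        key = {"channel_type": "channel_type", "music_type": "music_type",
               "channel_type:music_type": "channel_type * music_type"}
        for name, pg_name in key.items():
            row = theirs[theirs.Source == pg_name].iloc[0]
            assert mine.effects[name].statistic == pytest.approx(row.F,
                                                                 rel=1e-6)
            assert mine.effects[name].extra["p_uncorrected"] == \
                pytest.approx(row["p_unc"], rel=1e-6, abs=1e-12)
            assert mine.effects[name].extra["epsilon"] == \
                pytest.approx(row["eps"], rel=1e-6)
            assert mine.effects[name].p == pytest.approx(row["p_GG_corr"],
                                                         rel=1e-6, abs=1e-12)

    def test_missing_cell_rejected_with_subject_list(self):
        values = [[[1, 2], [3, 4]], [[2, 3], [5, 7]], [[1, 3], [4, 6]]]
        table = cell_table(values)
        table = table[~((table.subject == 2)
                        & (table.channel_type == "a2")
                        & (table.music_type == "b2"))]
        with pytest.raises(ValueError, match="2"):
            rm_anova_3x2(table)

    def test_summary_renders(self, rng):
        vals = rng.standard_normal((5, 3, 2))
        res = rm_anova_3x2(cell_table(vals, a_levels=("a1", "a2", "a3")))
        text = res.summary()
        assert "Repeated-measures ANOVA" in text and "eta2p" in text


class TestSimpleEffects:
    def test_identical_cells_give_zero_t(self):
        values = [[[1, 2], [1, 4]], [[2, 3], [2, 7]], [[3, 3], [3, 6]]]
        table = cell_table(values)
        res = simple_effects(table, within="channel_type",
                             at_factor="music_type", at_level="b1")
        assert res[0].statistic == 0.0

    def test_two_level_factor_reproduces_paired_t(self, rng):
        vals = rng.standard_normal((8, 2, 2))
        table = cell_table(vals)
        res = simple_effects(table, within="music_type",
                             at_factor="channel_type", at_level="a1")
        direct = paired_t(vals[:, 0, 0], vals[:, 0, 1])
        assert res[0].statistic == pytest.approx(direct.statistic, abs=1e-12)
        assert res[0].p == pytest.approx(direct.p, abs=1e-12)

    def test_holm_adjustment_monotone(self, rng):
        vals = rng.standard_normal((10, 3, 2))
        vals[:, 2, :] += 1.0
        table = cell_table(vals, a_levels=("a1", "a2", "a3"))
        res = simple_effects(table, within="channel_type",
                             at_factor="music_type", at_level="b1",
                             adjust="holm")
        for r in res:
            assert r.extra["p_holm"] >= r.p - 1e-15

    def test_missing_level_rejected(self):
        table = cell_table([[[1, 2], [3, 4]]] * 3)
        with pytest.raises(ValueError, match="no rows"):
            simple_effects(table, within="channel_type",
                           at_factor="music_type", at_level="zz")
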