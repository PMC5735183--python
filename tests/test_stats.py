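"""Statistics: transforms, t tests, Fisher, circular and linear ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from oculostim import (
    bonferroni_alpha,
    circ_descriptives,
    fisher_exact,
    hk_circ_anova,
    latency_test,
    reciprocal_transform,
    twoway_linear_anova,
    watson_williams,
)
from oculostim.errors import InvalidArgumentError, UnsupportedDesignError


class TestReciprocal:
    def test_arithmetic(self):
        assert reciprocal_transform([200.0])[0] == pytest.approx(5.0)
        assert reciprocal_transform([250.0])[0] == pytest.approx(4.0)

    def test_order_reversal(self, rng):
        lat = np.sort(rng.uniform(100, 400, 50))
        rates = reciprocal_transform(lat)
        assert np.all(np.diff(rates) < 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidArgumentError):
            reciprocal_transform([200.0, 0.0])


class TestLatencyTest:
    def test_hand_computed_pooled_t(self):
        # pooled s^2 = 1, t = -3 / sqrt(2/3) = -3.6742, df = 4
        res = latency_test([1, 2, 3], [4, 5, 6], method="t", transform=False)
        assert res.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.02131, abs=1e-4)
        assert res.extras["mean_diff_ms"] == pytest.approx(-3.0)

    def test_identical_groups_null(self):
        res = latency_test([1, 2, 3], [1, 2, 3], method="t", transform=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(InvalidArgumentError):
            latency_test([1, 2, 3], [1, 2], paired=True, transform=False)

    def test_zero_variance_flagged(self):
        res = latency_test([5.0, 5.0], [7.0, 7.0], method="t", transform=False)
        assert "zero-variance" in res.flags

    def test_ranksum_matches_scipy(self, rng):
        a = rng.uniform(100, 300, 40)
        b = rng.uniform(120, 320, 35)
        res = latency_test(a, b, method="ranksum", transform=False)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_transform_changes_statistic_sign(self):
        a = [150.0, 160.0, 170.0]
        b = [200.0, 210.0, 220.0]
        raw = latency_test(a, b, transform=False)
        rate = latency_test(a, b, transform=True)
        assert raw.statistic < 0 < rate.statistic  # faster group = higher rate

    def test_invariant_to_observation_order(self, rng):
        a = rng.uniform(100, 300, 30)
        b = rng.uniform(100, 300, 30)
        r1 = latency_test(a, b)
        r2 = latency_test(a[::-1], b[rng.permutation(30)])
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


def _fisher_oracle(table):
    """Exhaustive hypergeometric enumeration over the support."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    pmf = sps.hypergeom(N, r1, c1).pmf
    p_obs = pmf(a)
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = pmf(ks)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestFisherExact:
    def test_balanced_table_is_null(self):
        res = fisher_exact([[5, 5], [5, 5]])
        assert res.p_value == pytest.approx(1.0)
        assert res.effect_estimate == pytest.approx(1.0)

    def test_perfectly_separated_table(self):
        res = fisher_exact([[0, 5], [5, 0]])
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)
        assert res.effect_estimate == 0.0

    def test_matches_enumeration_and_scipy_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 41))
            cells = rng.multinomial(n, [0.25] * 4)
            table = [[int(cells[0]) , int(cells[1])], [int(cells[2]), int(cells[3])]]
            r1, r2 = sum(table[0]), sum(table[1])
            c1 = table[0][0] + table[1][0]
            if min(r1, r2, c1, n - c1) == 0:
                continue
            res = fisher_exact(table)
            assert res.p_value == pytest.approx(_fisher_oracle(table), abs=1e-12)
            ref_or, ref_p = sps.fisher_exact(table)
            assert res.p_value == pytest.approx(float(ref_p), abs=1e-12)

    def test_invalid_cells_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fisher_exact([[1, -2], [3, 4]])
        with pytest.raises(InvalidArgumentError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestCircDescriptives:
    def test_two_vector_geometry(self):
        cd = circ_descriptives([0.0, 90.0])
        assert cd.mean_direction_deg == pytest.approx(45.0)
        assert cd.resultant_length == pytest.approx(np.cos(np.pi / 4))

    def test_symmetric_angles_undefined_mean(self):
        cd = circ_descriptives([0.0, 90.0, 180.0, 270.0])
        assert cd.undefined and cd.resultant_length == 0.0

    def test_single_angle_identity(self):
        cd = circ_descriptives([123.0])
        assert cd.mean_direction_deg == pytest.approx(123.0)
        assert cd.resultant_length == pytest.approx(1.0)


class TestCircAnova:
    def _design(self, rng, n_a=2, n_b=2, n_cell=20, kappa=5.0, shift_a=0.0):
        angs, fa, fb = [], [], []
        for i in range(n_a):
            for j in range(n_b):
                angs.append(rng.vonmises(i * shift_a, kappa, n_cell))
                fa += [i] * n_cell
                fb += [j] * n_cell
        return np.rad2deg(np.concatenate(angs)), np.array(fa), np.array(fb)

    def test_degrees_of_freedom_4x2(self, rng):
        ang, fa, fb = self._design(rng, n_a=4, n_b=2)
        res = hk_circ_anova(ang, fa, fb, n_perm=0)
        assert (res.factor_a.df, res.factor_b.df, res.interaction.df) == (3, 1, 3)

    def test_strong_shift_detected_by_both_routes(self, rng):
        ang, fa, fb = self._design(rng, kappa=10.0, shift_a=np.pi / 2)
        res = hk_circ_anova(ang, fa, fb, n_perm=999, seed=0)
        assert res.factor_a.p_value < 0.001
        assert res.factor_a.p_permutation < 0.01

    def test_single_level_factor_collapses(self, rng):
        ang, fa, _ = self._design(rng, n_b=1)
        fb = np.zeros_like(fa)
        res = hk_circ_anova(ang, fa, fb, n_perm=0)
        assert res.factor_b.df == 0 and res.factor_b.p_value == 1.0
        assert res.interaction.df == 0

    def test_agrees_with_one_way_watson_williams(self, rng):
        """With factor B collapsed, the two-factor test should reach the same
        rejection decision as a one-way circular test almost always."""
        agree = 0
        reps = 200
        for i in range(reps):
            shift = 0.0 if i % 2 else float(rng.uniform(0.4, 1.2))
            ang, fa, _ = self._design(rng, n_b=1, n_cell=30, kappa=6.0,
                                      shift_a=shift)
            fb = np.zeros_like(fa)
            hk = hk_circ_anova(ang, fa, fb, n_perm=0)
            ww = watson_williams(ang, fa)
            agree += (hk.factor_a.p_value < 0.05) == (ww.p_value < 0.05)
        assert agree / reps >= 0.95

    def test_statistics_invariant_to_observation_order(self, rng):
        ang, fa, fb = self._design(rng)
        perm = rng.permutation(ang.size)
        r1 = hk_circ_anova(ang, fa, fb, n_perm=0)
        r2 = hk_circ_anova(ang[perm], fa[perm], fb[perm], n_perm=0)
        assert r1.factor_a.statistic == pytest.approx(r2.factor_a.statistic)
        assert r1.interaction.statistic == pytest.approx(r2.interaction.statistic)

    def test_low_kappa_flagged(self, rng):
        ang = np.rad2deg(rng.uniform(-np.pi, np.pi, 80))
        fa = np.repeat([0, 1], 40)
        fb = np.tile(np.repeat([0, 1], 20), 2)
        res = hk_circ_anova(ang, fa, fb, n_perm=0)
        assert res.low_kappa_warning and res.regime == "chi2"

    def test_empty_cell_unsupported(self, rng):
        ang = np.rad2deg(rng.vonmises(0, 5, 60))
        fa = np.repeat([0, 1], 30)
        fb = np.concatenate([np.repeat([0, 1], 15), np.zeros(30, int)])
        with pytest.raises(UnsupportedDesignError):
            hk_circ_anova(ang, fa, fb)


def _anova_oracle(y, fa, fb):
    """Hand-computed balanced two-way ANOVA sums of squares."""
    y = np.asarray(y, float)
    levels_a, levels_b = np.unique(fa), np.unique(fb)
    gm = y.mean()
    n_cell = len(y) / (len(levels_a) * len(levels_b))
    ss_a = sum(
        (y[fa == a].mean() - gm) ** 2 * (fa == a).sum() for a in levels_a
    )
    ss_b = sum(
        (y[fb == b].mean() - gm) ** 2 * (fb == b).sum() for b in levels_b
    )
    ss_cells = sum(
        (y[(fa == a) & (fb == b)].mean() - gm) ** 2 * n_cell
        for a in levels_a
        for b in levels_b
    )
    ss_int = ss_cells - ss_a - ss_b
    ss_res = sum(
        ((y[(fa == a) & (fb == b)] - y[(fa == a) & (fb == b)].mean()) ** 2).sum()
        for a in levels_a
        for b in levels_b
    )
    df_a, df_b = len(levels_a) - 1, len(levels_b) - 1
    df_int = df_a * df_b
    df_res = len(y) - len(levels_a) * len(levels_b)
    ms_res = ss_res / df_res
    return (ss_a / df_a / ms_res, ss_b / df_b / ms_res, ss_int / df_int / ms_res)


class TestLinearAnova:
    def test_matches_hand_computed_sums_of_squares(self, rng):
        fa = np.repeat([0, 1], 6)
        fb = np.tile(np.repeat([0, 1], 3), 2)
        y = rng.normal(10, 2, 12) + 3 * fa + 1.5 * fb
        res = twoway_linear_anova(y, fa, fb)
        f_a, f_b, f_i = _anova_oracle(y, fa, fb)
        assert res["factor_a"].statistic == pytest.approx(f_a, abs=1e-10)
        assert res["factor_b"].statistic == pytest.approx(f_b, abs=1e-10)
        assert res["interaction"].statistic == pytest.approx(f_i, abs=1e-10)

    def test_location_invariance(self, rng):
        fa = np.repeat([0, 1], 10)
        fb = np.tile([0, 1], 10)
        y = rng.normal(size=20)
        r1 = twoway_linear_anova(y, fa, fb)
        r2 = twoway_linear_anova(y + 100.0, fa, fb)
        assert r1["factor_a"].statistic == pytest.approx(r2["factor_a"].statistic)
        assert r1["factor_a"].p_value == pytest.approx(r2["factor_a"].p_value)

    def test_label_permutation_symmetry(self, rng):
        fa = np.repeat([0, 1], 10)
        fb = np.tile([0, 1], 10)
        y = rng.normal(size=20)
        r1 = twoway_linear_anova(y, fa, fb)
        r2 = twoway_linear_anova(y, 1 - fa, fb)
        assert r1["factor_a"].statistic == pytest.approx(r2["factor_a"].statistic)

    def test_constant_response_flagged(self):
        fa = np.repeat([0, 1], 6)
        fb = np.tile([0, 1], 6)
        res = twoway_linear_anova(np.ones(12), fa, fb)
        assert "constant-response" in res["factor_a"].flags


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 4, 0.0125), (0.05, 8, 0.00625), (0.05, 1, 0.05)]
    )
    def test_adjustment(self, alpha, n, expected):
        assert bonferroni_alpha(alpha, n) == pytest.approx(expected)

    def test_invalid_count(self):
        with pytest.raises(InvalidArgumentError):
            bonferroni_alpha(0.05, 0)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20)
def test_p_values_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(100, 400, 12)
    b = rng.uniform(100, 400, 15)
    for method in ("t", "ranksum"):
        res = latency_test(a, b, method=method)
        assert 0.0 <= res.p_value <= 1.0
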