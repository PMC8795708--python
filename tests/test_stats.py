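import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h
from scipy import stats as sps

from nirslat.stats import (bh_fdr, channel_t_map, ks_two_sample,
                           laterality_index, paired_t_power,
                           pearson_li_correlation, required_n_paired_t,
                           rm_anova2, roi_mean, separation_inconsistency_cm,
                           t_test)


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_bh(p, q):
    """Step-up FDR by direct enumeration of the rejection rule."""
    p = np.asarray(p)
    order = np.argsort(p)
    m = len(p)
    k_max = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i / m * q:
            k_max = i
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


def hand_rm_anova_ss(y):
    """Sums-of-squares decomposition by explicit summation loops."""
    n, a, b = y.shape
    gm = y.mean()
    ss = dict(A=0.0, B=0.0, AB=0.0, AS=0.0, BS=0.0, ABS=0.0)
    m_a = [y[:, i, :].mean() for i in range(a)]
    m_b = [y[:, :, j].mean() for j in range(b)]
    m_s = [y[s].mean() for s in range(n)]
    for i in range(a):
        ss["A"] += n * b * (m_a[i] - gm) ** 2
    for j in range(b):
        ss["B"] += n * a * (m_b[j] - gm) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (y[:, i, j].mean() - m_a[i] - m_b[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (y[s, i, :].mean() - m_s[s] - m_a[i] + gm) ** 2
        for j in range(b):
            ss["BS"] += a * (y[s, :, j].mean() - m_s[s] - m_b[j] + gm) ** 2
    for s in range(n):
        for i in range(a):
            for j in range(b):
                ss["ABS"] += (y[s, i, j] - y[s, i, :].mean() - y[s, :, j].mean()
                              - y[:, i, j].mean() + m_a[i] + m_b[j] + m_s[s]
                              - gm) ** 2
    f_a = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    f_b = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    f_ab = (ss["AB"] / ((a - 1) * (b - 1))) / (ss["ABS"] / ((a - 1) * (b - 1) * (n - 1)))
    return f_a, f_b, f_ab


def ecdf_ks_d(x, y):
    """D = sup |ECDF1 - ECDF2| by enumeration over all observed points."""
    pts = np.concatenate([x, y])
    return max(abs((x <= t).mean() - (y <= t).mean()) for t in pts)


def _anova_frame(y):
    n, a, b = y.shape
    rows = [{"subj": s, "A": f"a{i}", "B": f"b{j}", "y": y[s, i, j]}
            for s in range(n) for i in range(a) for j in range(b)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

class TestRoiMeanAndLI:
    def test_roi_mean_examples(self):
        s = pd.Series({1: 1.0, 2: 2.0, 3: 3.0})
        assert roi_mean(s, [2]) == 2.0
        assert roi_mean(s, [1, 2, 3]) == 2.0
        assert roi_mean(s, [1, 2, 99]) == 1.5  # pruned channel ignored
        with pytest.raises(ValueError, match="no retained"):
            roi_mean(s, [98, 99])

    @pytest.mark.parametrize("L,R,li", [(0.5, 0.5, 0.0), (1.0, 0.0, 1.0),
                                        (3.0, 1.0, 0.5), (0.0, 1.0, -1.0)])
    def test_laterality_index_examples(self, L, R, li):
        assert laterality_index(L, R) == pytest.approx(li)

    def test_undefined_when_sum_vanishes(self):
        with pytest.raises(ValueError, match="undefined"):
            laterality_index(1e-14, -1e-14)

    @given(st_h.floats(-10, 10), st_h.floats(-10, 10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry(self, L, R):
        if abs(L + R) < 1e-6:
            return
        assert laterality_index(L, R) == pytest.approx(
            -laterality_index(R, L), rel=1e-9)


class TestChannelTMap:
    def test_hand_computed_t(self):
        resp = pd.DataFrame({10: [1.0, 2.0, 3.0]})
        amap = channel_t_map(resp)
        row = amap.table.iloc[0]
        assert row["t"] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-6)
        assert row["t"] == pytest.approx(3.4641016, rel=1e-6)

    def test_sign_flip_negates_t_keeps_p(self, rng):
        resp = pd.DataFrame(rng.normal(0.2, 1.0, (10, 4)), columns=[1, 2, 3, 4])
        a = channel_t_map(resp).table
        b = channel_t_map(-resp).table
        assert np.allclose(a["t"], -b["t"])
        assert np.allclose(a["p"], b["p"])

    def test_degenerate_channels_flagged(self):
        resp = pd.DataFrame({1: [0.0, 0.0, 0.0], 2: [1.0, 1.0, 1.0]})
        t = channel_t_map(resp).table.set_index("channel_id")
        assert np.isnan(t.loc[1, "t"]) and t.loc[1, "degenerate"]
        assert np.isinf(t.loc[2, "t"]) and t.loc[2, "p"] == 0.0

    def test_adjusted_significant_subset_of_raw(self, rng):
        resp = pd.DataFrame(rng.normal(0.1, 1.0, (12, 20)),
                            columns=range(20))
        tab = channel_t_map(resp, q=0.05).table
        assert set(tab.loc[tab.significant, "channel_id"]) <= set(
            tab.loc[tab.p < 0.05, "channel_id"])


class TestBhFdr:
    def test_published_examples(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05).all()
        assert not bh_fdr([0.2, 0.8], q=0.05).any()
        assert bh_fdr([0.04], q=0.05)[0]

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(300):
            m = rng.integers(1, 21)
            p = np.round(rng.uniform(0, 1, m), 3)
            q = rng.choice([0.01, 0.05, 0.1, 0.25])
            assert np.array_equal(bh_fdr(p, q), brute_force_bh(p, q))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestTTest:
    def test_one_sample_hand_value(self):
        res = t_test([1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(3.4641016, rel=1e-6)
        assert res.df == 2

    def test_symmetric_sample_gives_zero_t(self):
        res = t_test([-2.0, 2.0, -1.0, 1.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_paired_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)

    def test_paired_matches_scipy(self, rng):
        x, y = rng.normal(size=(2, 15))
        res = t_test(x, y, paired=True)
        ref = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestRmAnova2:
    @pytest.mark.parametrize("shape", [(3, 2, 2), (4, 2, 3), (5, 3, 3),
                                       (2, 2, 2), (5, 2, 3)])
    def test_matches_hand_sums_of_squares(self, rng, shape):
        y = rng.normal(size=shape)
        res = rm_anova2(_anova_frame(y), "y", ("A", "B"), "subj")
        f_a, f_b, f_ab = hand_rm_anova_ss(y)
        assert res["A"].statistic == pytest.approx(f_a, rel=1e-9)
        assert res["B"].statistic == pytest.approx(f_b, rel=1e-9)
        assert res["interaction"].statistic == pytest.approx(f_ab, rel=1e-9)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=(6, 2, 3))
        df = _anova_frame(y)
        res = rm_anova2(df, "y", ("A", "B"), "subj")
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subj",
                          detailed=True)
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        for name, key in (("A", "A"), ("B", "B"), ("A * B", "interaction")):
            row = ref[ref["Source"] == name].iloc[0]
            assert res[key].statistic == pytest.approx(row["F"], rel=1e-6)
            assert res[key].p_value == pytest.approx(row[pcol], rel=1e-6)

    def test_additive_cell_means_give_zero_interaction_f(self, rng):
        n, a, b = 6, 2, 3
        subj = rng.normal(size=n)
        ai = np.array([1.0, -1.0])
        bj = np.array([0.5, 0.0, -0.5])
        y = subj[:, None, None] + ai[None, :, None] + bj[None, None, :]
        # subject-level noise centred within every cell: the cell means stay
        # exactly additive (interaction SS = 0) while the error SS is positive
        z = rng.normal(size=(n, a, b))
        y = y + z - z.mean(axis=0, keepdims=True)
        res = rm_anova2(_anova_frame(y), "y", ("A", "B"), "subj")
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-9)

    def test_tukey_posthoc_flags_separated_cells(self, rng):
        y = rng.normal(0, 0.1, size=(8, 2, 2))
        y[:, 1, :] += 5.0  # huge main effect of A
        res = rm_anova2(_anova_frame(y), "y", ("A", "B"), "subj")
        ph = res["interaction"].post_hoc
        big = ph[(ph.cell_1 == ("a0", "b0")) & (ph.cell_2 == ("a1", "b0"))]
        assert big.iloc[0]["p_tukey"] < 0.001

    def test_single_subject_rejected(self, rng):
        y = rng.normal(size=(1, 2, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova2(_anova_frame(y), "y", ("A", "B"), "subj")

    def test_missing_cells_rejected(self, rng):
        df = _anova_frame(rng.normal(size=(4, 2, 2)))
        df = df[~((df.subj == 0) & (df.A == "a0") & (df.B == "b1"))]
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova2(df, "y", ("A", "B"), "subj")


class TestPearsonCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_li_correlation(x, 2 * x)
        assert res.statistic == pytest.approx(1.0)

    def test_gross_outlier_excluded_and_fit_restored(self, rng):
        x = rng.uniform(-1, 1, 21)
        y = x + rng.normal(0, 0.01, 21)
        y[20] = y[20] + 10 * 1.0  # ~10 SD residual
        res = pearson_li_correlation(x, y, exclude_outliers=True)
        assert 20 in res.effect["excluded"]
        assert res.effect["r_post_exclusion"] >= 0.99

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_li_correlation(np.ones(10), np.arange(10.0))

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=(2, 30))
        res = pearson_li_correlation(x, y)
        r, p = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(r)
        assert res.p_value == pytest.approx(p)


class TestKsTwoSample:
    def test_identical_samples_give_zero_d(self, rng):
        x = rng.normal(size=50)
        assert ks_two_sample(x, x).statistic == 0.0

    def test_disjoint_supports_give_unit_d(self):
        assert ks_two_sample([1, 2, 3], [10, 11, 12]).statistic == 1.0

    def test_hand_enumerated_d(self):
        res = ks_two_sample([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.statistic == pytest.approx(0.25)

    def test_matches_ecdf_enumeration(self, rng):
        for _ in range(50):
            x = rng.normal(size=rng.integers(5, 30))
            y = rng.normal(0.5, 1.2, size=rng.integers(5, 30))
            assert ks_two_sample(x, y).statistic == pytest.approx(
                ecdf_ks_d(x, y), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ks_two_sample([], [1.0])


class TestPowerAnalysis:
    def test_published_sample_size(self):
        assert required_n_paired_t(0.5, 0.05, 0.95) == 54

    def test_lower_power_smaller_n(self):
        # oracle: scan of the noncentral-t power curve (statsmodels agrees)
        assert required_n_paired_t(0.5, 0.05, 0.80) == 34

    def test_huge_effect_hits_floor(self):
        assert required_n_paired_t(5.0, 0.05, 0.80) <= 4

    def test_power_curve_matches_statsmodels(self):
        from statsmodels.stats.power import TTestPower
        for n in (10, 30, 54):
            ref = TTestPower().power(effect_size=0.5, nobs=n, alpha=0.05)
            assert paired_t_power(n, 0.5) == pytest.approx(ref, abs=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            required_n_paired_t(-0.5)
        with pytest.raises(ValueError):
            required_n_paired_t(0.5, 0.05, 0.04)


def test_optode_separation_inconsistency_arithmetic():
    # (60 - 53.5)/60 x 3 cm, one decimal
    assert separation_inconsistency_cm(53.5, 60.0, 3.0) == 0.3
    with pytest.raises(ValueError):
        separation_inconsistency_cm(-1.0, 60.0)
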