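"""Unit tests for imputation, transforms, Welch tests, BH and SVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rhizolink import (
    bh_adjust,
    blank_filter,
    differential_metabolites,
    impute_half_min,
    ks_normality,
    log_z_transform,
    sva_correct,
    welch_anova,
    welch_two_sample,
)
from rhizolink.preprocess import ZeroVarianceError

from conftest import make_matrix


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImputeHalfMin:
    def test_missing_becomes_half_minimum(self):
        m = make_matrix([[100.0, np.nan, 40.0]], ["A"], n_replicates=3)
        out = impute_half_min(m)
        assert out.intensities.iloc[0, 1] == 20.0

    def test_fully_observed_matrix_unchanged(self):
        m = make_matrix(np.abs(np.random.default_rng(0).normal(100, 10, (4, 6))),
                        ["A", "B"], n_replicates=3)
        out = impute_half_min(m)
        pd.testing.assert_frame_equal(out.intensities, m.intensities)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(100, 30, (10, 9)))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        vals[:, 0] = 50.0  # guarantee one observation per feature
        m = make_matrix(vals, ["A", "B", "C"], n_replicates=3)
        out = impute_half_min(m)
        mask = ~np.isnan(vals)
        assert np.array_equal(out.intensities.to_numpy()[mask], vals[mask])
        assert not out.intensities.isna().any().any()

    def test_all_missing_feature_raises(self):
        m = make_matrix([[np.nan, np.nan, np.nan]], ["A"], n_replicates=3)
        with pytest.raises(ValueError, match="zero observed"):
            impute_half_min(m)


# ---------------------------------------------------------------------------
# log / z transform and KS QC
# ---------------------------------------------------------------------------

class TestLogZTransform:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        m = make_matrix(np.exp(rng.normal(5, 1, (8, 12))), ["A", "B", "C", "D"])
        out = log_z_transform(m)
        Z = out.intensities.to_numpy()
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(Z.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_constant_feature_dropped_with_warning(self, caplog):
        vals = np.vstack([np.full(6, 100.0), np.exp(np.random.default_rng(0).normal(5, 1, 6))])
        m = make_matrix(vals, ["A", "B"])
        out = log_z_transform(m)
        assert list(out.intensities.index) == ["F002"]
        with pytest.raises(ZeroVarianceError):
            log_z_transform(m, on_zero_variance="error")

    def test_ranking_within_feature_preserved(self):
        rng = np.random.default_rng(3)
        vals = np.abs(rng.normal(100, 40, (5, 9))) + 1
        m = make_matrix(vals, ["A", "B", "C"])
        out = log_z_transform(m)
        for i in range(5):
            assert np.array_equal(
                np.argsort(vals[i]), np.argsort(out.intensities.to_numpy()[i])
            )


class TestKsNormality:
    def test_pvalues_uniform_under_normality(self):
        # 1000 standard-normal features of n=57: KS p-values should be uniform
        rng = np.random.default_rng(4)
        m = make_matrix(rng.standard_normal((1000, 57)), [f"A{i}" for i in range(19)],
                        transformed=True)
        p = ks_normality(m)
        assert stats.kstest(p.to_numpy(), "uniform").pvalue > 1e-3

    def test_constant_feature_reported_na(self):
        m = make_matrix([[1.0, 1.0, 1.0]], ["A"], transformed=True)
        assert np.isnan(ks_normality(m).iloc[0])

    def test_heavy_tailed_feature_rejected(self):
        rng = np.random.default_rng(5)
        x = rng.standard_t(1, size=570)
        m = make_matrix(x[None, :], [f"A{i}" for i in range(190)], transformed=True)
        assert ks_normality(m).iloc[0] < 1e-6


# ---------------------------------------------------------------------------
# Welch tests
# ---------------------------------------------------------------------------

def _welch_t_oracle(a, b):
    """Textbook two-sample Welch t with Welch–Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


def _welch_anova_oracle(groups):
    """Independent re-implementation of the heteroscedastic one-way statistic."""
    k = len(groups)
    n = np.array([len(g) for g in groups], float)
    m = np.array([np.mean(g) for g in groups])
    s2 = np.array([np.var(g, ddof=1) for g in groups])
    w = n / s2
    mw = np.sum(w * m) / np.sum(w)
    A = np.sum(w * (m - mw) ** 2) / (k - 1)
    S = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    F = A / (1 + 2 * (k - 2) / (k**2 - 1) * S)
    df2 = (k**2 - 1) / (3 * S)
    return F, k - 1, df2, stats.f.sf(F, k - 1, df2)


class TestWelch:
    def test_two_sample_matches_textbook_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 8))
            b = rng.normal(0.5, 2, rng.integers(3, 8))
            res = welch_two_sample(a, b)
            t, df, p = _welch_t_oracle(a, b)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.df2 == pytest.approx(df, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_identical_samples_give_t0_p1(self):
        res = welch_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0
        assert res.p == 1

    def test_large_shift_detected(self):
        res = welch_two_sample([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.p < 0.05

    def test_anova_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = [rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(3, 7))
                      for _ in range(5)]
            res = welch_anova(groups)
            F, df1, df2, p = _welch_anova_oracle(groups)
            assert res.statistic == pytest.approx(F, abs=1e-10)
            assert res.df2 == pytest.approx(df2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_anova_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.3, 1 + i * 0.2, 4 + i) for i in range(4)]
        res = welch_anova(groups)
        df = pd.DataFrame(
            {"y": np.concatenate(groups),
             "g": np.repeat(range(4), [len(g) for g in groups])}
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-10)
        assert res.p == pytest.approx(float(ref["p_unc"][0]), rel=1e-10)

    def test_equal_group_means_give_f0_p1(self):
        res = welch_anova([[1.0, 2.0, 3.0]] * 3)
        assert res.statistic == 0
        assert res.p == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_k2_anova_is_squared_welch_t(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 9))
        b = rng.normal(1, 3, rng.integers(3, 9))
        F = welch_anova([a, b]).statistic
        t = welch_two_sample(a, b).statistic
        assert abs(F - t**2) < 1e-9

    def test_degenerate_groups_raise(self):
        with pytest.raises(ZeroVarianceError):
            welch_anova([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ZeroVarianceError):
            welch_anova([[1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ZeroVarianceError):
            welch_two_sample([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Naive O(m^2) step-up adjustment straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
        )
    return adj


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_constant_mp_over_rank(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(_bh_oracle(p), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# blank filter
# ---------------------------------------------------------------------------

class TestBlankFilter:
    def _matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        accs = [f"A{i}" for i in range(5)]
        n_cols = 5 * 3 + 3
        vals = rng.standard_normal((30, n_cols))  # null features
        signal = rng.standard_normal(n_cols)
        signal[0:3] += 10  # elevated in accession A0 only
        vals = np.vstack([vals, signal])
        return make_matrix(vals, accs, n_blanks=3, transformed=True)

    def test_differential_feature_retained_flat_removed(self):
        m = self._matrix()
        res = blank_filter(m, alpha=0.05)
        assert "F031" in res.retained  # the planted signal
        # features identical in distribution across accessions and blank
        assert len(res.retained) <= 3

    def test_no_blanks_raises(self):
        m = make_matrix(np.random.default_rng(0).standard_normal((3, 6)),
                        ["A", "B"], transformed=True)
        with pytest.raises(ValueError, match="blank"):
            blank_filter(m)

    def test_recovers_exudate_features_on_synthetic_data(self, default_result,
                                                         default_dataset):
        # generator truth: background features are shared with the blank and
        # should mostly be removed; planted exudate features must survive
        retained = set(default_result.retained_features)
        for link in default_dataset.truth:
            assert link.feature_id in retained


# ---------------------------------------------------------------------------
# surrogate-variable correction
# ---------------------------------------------------------------------------

class TestSvaCorrect:
    def _batch_matrix(self, shift=2.0, seed=11):
        rng = np.random.default_rng(seed)
        accs = [f"A{i}" for i in range(6)]
        n = 6 * 3
        acc_eff = np.repeat(rng.normal(0, 1, (40, 6)), 3, axis=1)
        batch = np.tile([0.0, shift, 0.0], 6)  # replicate 2 = batch 2 shifted
        vals = acc_eff + batch[None, :] + rng.normal(0, 0.3, (40, n))
        return make_matrix(vals, accs, transformed=True), acc_eff

    def test_forced_zero_surrogates_is_identity(self):
        m, _ = self._batch_matrix()
        out = sva_correct(m, n_sv=0)
        pd.testing.assert_frame_equal(out.corrected.intensities, m.intensities)
        assert out.n_sv == 0

    def test_batch_shift_removed(self):
        m, _ = self._batch_matrix()
        res = sva_correct(m, n_sv="auto", seed=0)
        assert res.n_sv >= 1
        batch = m.samples["batch"].to_numpy()
        def batch_gap(X):
            g2 = X[:, batch == 2].mean()
            g1 = X[:, batch != 2].mean()
            return abs(g2 - g1)
        before = batch_gap(m.intensities.to_numpy())
        after = batch_gap(res.corrected.intensities.to_numpy())
        assert after < 0.1 * before

    def test_accession_effects_preserved(self):
        m, acc_eff = self._batch_matrix()
        res = sva_correct(m, n_sv="auto", seed=0)
        groups = m.samples["accession"].to_numpy()
        levels = list(dict.fromkeys(groups))
        def acc_means(X):
            return np.stack([X[:, groups == g].mean(axis=1) for g in levels], axis=1)
        before = acc_means(m.intensities.to_numpy())
        after = acc_means(res.corrected.intensities.to_numpy())
        r = np.corrcoef(before.ravel(), after.ravel())[0, 1]
        assert r > 0.95

    def test_too_many_surrogates_rejected(self):
        m, _ = self._batch_matrix()
        with pytest.raises(ValueError):
            sva_correct(m, n_sv=12)  # 18 samples - 6 accessions = 12 df


# ---------------------------------------------------------------------------
# differential metabolites
# ---------------------------------------------------------------------------

class TestDifferentialMetabolites:
    def test_shifted_compound_detected_equal_not(self):
        rng = np.random.default_rng(12)
        accs = [f"A{i}" for i in range(19)]
        acc_of = pd.Series(np.repeat(accs, 3), index=[f"s{i}" for i in range(57)])
        areas = pd.DataFrame(rng.standard_normal((20, 57)),
                             index=[f"C{i}" for i in range(20)], columns=acc_of.index)
        areas.iloc[0, 0:3] += 5  # compound shifted in one accession by 5 sd
        tab = differential_metabolites(areas, acc_of)
        tab = tab.set_index("compound_id")
        assert tab.loc["C0", "significant"]
        assert not tab.loc["C1", "significant"]
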