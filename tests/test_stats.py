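"""Statistics tests: gates, Welch/Mann-Whitney/RM-ANOVA/Friedman, expression.

Independent oracles: brute-force permutation enumeration for Mann-Whitney,
direct sums-of-squares for RM-ANOVA (cross-checked against pingouin), the
textbook rank-sum formula for Friedman, and hand-computed Welch values.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ratafib as rf
from ratafib.stats import NONPARAMETRIC, PARAMETRIC


def mw_exact_oracle(x, y):
    """Full enumeration of the two-sided Mann-Whitney p, ties included.

    Independent of the implementation under test: U is computed by pair
    counting (greater + half ties), and the null distribution by explicitly
    enumerating every split of the pooled values.
    """
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)

    def u_of(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        gt = np.sum(xs[:, None] > ys[None, :])
        eq = np.sum(xs[:, None] == ys[None, :])
        return gt + 0.5 * eq

    u_obs = u_of(range(nx))
    mu = nx * (n - nx) / 2.0
    devs = [abs(u_of(c) - mu) for c in itertools.combinations(range(n), nx)]
    return float(np.mean(np.array(devs) >= abs(u_obs - mu) - 1e-9))


class TestNormalityGate:
    def test_large_gaussian_sample_reads_parametric(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(0, 1, 50)
            hits += rf.normality_gate(x) == PARAMETRIC
        assert hits >= 18

    def test_lognormal_sample_reads_nonparametric(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).lognormal(0, 1, 20)
            hits += rf.normality_gate(x) == NONPARAMETRIC
        assert hits >= 16

    def test_constant_vector_warns_nonparametric(self):
        with pytest.warns(UserWarning):
            assert rf.normality_gate(np.full(10, 3.0)) == NONPARAMETRIC

    def test_tiny_sample_warns_nonparametric(self):
        with pytest.warns(UserWarning):
            assert rf.normality_gate([1.0, 2.0]) == NONPARAMETRIC


class TestWelch:
    def test_hand_computed_example(self):
        res = rf.welch_t([1, 2, 3], [2, 3, 4])
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == pytest.approx(4.0)

    def test_identical_groups_give_t0_p1(self):
        res = rf.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_large_shift_with_tiny_variance_is_overwhelming(self):
        x = np.array([1.0, 1.001, 0.999, 1.002])
        res = rf.welch_t(x, x + 10)
        assert res.p < 1e-4

    def test_zero_variance_in_both_groups_rejected(self):
        with pytest.raises(ValueError):
            rf.welch_t([1.0, 1.0], [2.0, 2.0])

    def test_agrees_with_scipy(self):
        from scipy import stats as sst

        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 6)
        res = rf.welch_t(x, y)
        ref = sst.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 7), rng.normal(1, 1, 5)
        p0 = rf.welch_t(x, y).p
        p1 = rf.welch_t(a * x + b, a * y + b).p
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestMannWhitney:
    def test_disjoint_groups_exact_p(self):
        res = rf.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_interleaved_symmetric_groups_give_p1(self):
        res = rf.mann_whitney([1, 4, 5, 8], [2, 3, 6, 7])
        assert res.statistic == pytest.approx(4 * 4 / 2)  # central U
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 6), rng.integers(2, 6)
        # integer draws force ties regularly
        x = rng.integers(0, 6, nx).astype(float)
        y = rng.integers(0, 6, ny).astype(float)
        res = rf.mann_whitney(x, y)
        assert res.method == "mann_whitney_exact"
        assert res.p == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)

    def test_rank_transform_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 6), rng.normal(1, 1, 5)
        p0 = rf.mann_whitney(x, y).p
        p1 = rf.mann_whitney(np.exp(x), np.exp(y)).p  # strictly monotone map
        assert p0 == pytest.approx(p1)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        res = rf.mann_whitney(x, y)
        assert res.method == "mann_whitney_normal"
        assert 0 <= res.p <= 1


class TestRMAnova:
    def test_zero_within_subject_deviation_gives_f0(self):
        m = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 9.0, 9.0]])
        res = rf.rm_anova(m)
        assert res.statistic == 0.0

    def test_3x3_sums_of_squares_oracle(self):
        m = np.array([[3.0, 5.0, 4.0], [6.0, 9.0, 8.0], [2.0, 5.0, 5.0]])
        res = rf.rm_anova(m)
        # independent second-path computation
        grand = m.mean()
        ss_p = 3 * np.sum((m.mean(0) - grand) ** 2)
        ss_s = 3 * np.sum((m.mean(1) - grand) ** 2)
        ss_e = np.sum((m - grand) ** 2) - ss_p - ss_s
        f = (ss_p / 2) / (ss_e / 4)
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.df == (2, 4)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        m = rng.normal(0, 1, (7, 4)) + np.array([0.0, 0.3, 0.6, 0.9])
        res = rf.rm_anova(m)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(7), 4),
                "period": np.tile(np.arange(4), 7),
                "value": m.ravel(),
            }
        )
        ref = pg.rm_anova(data=df, dv="value", within="period", subject="subject")
        assert res.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            rf.rm_anova(m)


class TestFriedman:
    def test_strictly_increasing_4x3_gives_chi2_8(self):
        m = np.array([[1, 2, 3], [1, 2, 3], [2, 4, 6], [0, 5, 9]], dtype=float)
        res = rf.friedman(m)
        assert res.statistic == pytest.approx(8.0)
        assert res.df == 2

    def test_all_tied_matrix_is_degenerate(self):
        res = rf.friedman(np.ones((4, 3)))
        assert res.statistic == 0.0
        assert np.isnan(res.p)
        assert any("degenerate" in w for w in res.warnings)

    def test_agrees_with_scipy_on_untied_data(self):
        from scipy import stats as sst

        rng = np.random.default_rng(9)
        m = rng.normal(0, 1, (8, 4))
        res = rf.friedman(m)
        ref = sst.friedmanchisquare(*[m[:, j] for j in range(4)])
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_two_periods_rejected(self):
        with pytest.raises(ValueError):
            rf.friedman(np.ones((5, 2)))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(10)
        m = rng.normal(0, 1, (6, 4))
        res0 = rf.friedman(m)
        res1 = rf.friedman(np.exp(m))
        assert res0.statistic == pytest.approx(res1.statistic)


class TestTrendDispatch:
    def test_strong_trend_detected_by_both_routes(self):
        rng = np.random.default_rng(11)
        m = rng.normal(0, 0.5, (7, 4)) + np.array([0.0, 2.0, 4.0, 6.0])
        assert rf.within_group_trend(m).p < 0.01
        assert rf.rm_anova(m).p < 0.01
        assert rf.friedman(m).p < 0.05

    def test_constant_matrix_reports_degenerate(self):
        res = rf.within_group_trend(np.full((5, 4), 2.0))
        assert res.method == "degenerate"
        assert np.isnan(res.p)


class TestExpression:
    def _records(self):
        rows = []
        for i, (g, hk) in enumerate(
            [("af", 100.0), ("af", 200.0), ("af", 150.0),
             ("control", 120.0), ("control", 80.0), ("control", 90.0)]
        ):
            a = f"a{i}"
            rows.append({"animal": a, "group": g, "gene": "GAPDH", "raw_level": hk})
            rows.append({"animal": a, "group": g, "gene": "Hcn4", "raw_level": hk * (1.4 if g == "af" else 1.3)})
        return pd.DataFrame(rows)

    def test_gene_equal_to_gapdh_normalizes_to_one(self):
        df = self._records()
        df.loc[df.gene == "Hcn4", "raw_level"] = df.loc[
            df.gene == "Hcn4", "animal"
        ].map(df[df.gene == "GAPDH"].set_index("animal")["raw_level"])
        norm, _, _ = rf.relative_expression(df)
        assert np.allclose(norm["normalized"], 1.0)

    def test_ratio_recovery_and_welch_comparison(self):
        norm, summary, tests = rf.relative_expression(self._records())
        af = summary[(summary.gene == "Hcn4") & (summary.group == "af")]
        assert af["mean"].iloc[0] == pytest.approx(1.4)
        assert "Hcn4" in tests

    def test_zero_gapdh_excludes_animal_with_warning(self):
        df = self._records()
        df.loc[(df.animal == "a0") & (df.gene == "GAPDH"), "raw_level"] = 0.0
        with pytest.warns(UserWarning):
            norm, summary, _ = rf.relative_expression(df)
        assert "a0" not in set(norm["animal"])
        af = summary[(summary.gene == "Hcn4") & (summary.group == "af")]
        assert af["n"].iloc[0] == 2

    def test_cohort_generator_recovery_of_programmed_means(self):
        # group means 1.42 (n=7) vs 1.35 (n=5) recovered within 2 SEM
        df = rf.generate_expression_cohort(seed=12)
        _, summary, tests = rf.relative_expression(df)
        row = summary[(summary.gene == "Hcn4") & (summary.group == "af")]
        assert abs(row["mean"].iloc[0] - 1.42) < 2 * 0.02 * np.sqrt(7)
        row = summary[(summary.gene == "Hcn4") & (summary.group == "control")]
        assert abs(row["mean"].iloc[0] - 1.35) < 2 * 0.01 * np.sqrt(5)

    def test_log2_path(self):
        norm, _, _ = rf.relative_expression(self._records(), method="log2")
        assert np.allclose(
            norm[norm.group == "af"]["normalized"], np.log2(1.4), atol=1e-12
        )
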