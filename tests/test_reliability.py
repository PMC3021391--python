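"""Reliability battery: correlations, sign tests, ANOVA, posterior-corr summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from motordcm.reliability import (
    ParamPanel,
    b_over_a_ratio,
    cross_session_correlation,
    ks_normality,
    matrix_session_agreement,
    parameter_anova,
    posterior_corr_group_summary,
    round_half_up,
    sign_consistency_test,
)


def make_panel(values: np.ndarray, groups=None) -> ParamPanel:
    """values: subjects x sessions x parameters."""
    n, s, c = values.shape
    groups = groups or ["g1"] * n
    rows = []
    for i in range(n):
        for j in range(s):
            for k in range(c):
                rows.append(
                    (f"s{i:02d}", groups[i], f"S{j}", f"p{k}", values[i, j, k])
                )
    return ParamPanel(
        pd.DataFrame(rows, columns=["subject", "group", "session", "parameter", "value"])
    )


class TestRounding:
    @pytest.mark.parametrize(
        "x, d, expected",
        [(2.25, 1, 2.3), (3.2667, 1, 3.3), (1.6667, 1, 1.7), (-2.25, 1, -2.3), (0.05, 1, 0.1)],
    )
    def test_half_up(self, x, d, expected):
        assert round_half_up(x, d) == pytest.approx(expected)


class TestSignConsistency:
    @pytest.mark.parametrize(
        "n_same, n_total, chi_1dp",
        [(11, 15, 3.3), (11, 16, 2.3), (10, 15, 1.7), (8, 16, 0.0), (14, 15, 11.3)],
    )
    def test_printed_statistics(self, n_same, n_total, chi_1dp):
        res = sign_consistency_test(n_same, n_total)
        assert round_half_up(res.chi_sq, 1) == pytest.approx(chi_1dp)
        assert res.df == 1

    def test_p_value(self):
        res = sign_consistency_test(11, 15)
        assert res.p == pytest.approx(0.07, abs=0.005)

    @given(n_total=st.integers(1, 60), n_same=st.integers(0, 60))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_bounds(self, n_total, n_same):
        if n_same > n_total:
            with pytest.raises(ValueError):
                sign_consistency_test(n_same, n_total)
            return
        res = sign_consistency_test(n_same, n_total)
        mirror = sign_consistency_test(n_total - n_same, n_total)
        assert res.chi_sq == pytest.approx(mirror.chi_sq)
        assert res.chi_sq >= 0
        assert 0 <= res.p <= 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            sign_consistency_test(1, 0)


class TestCrossSessionCorrelation:
    def test_identical_sessions(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(10, 1, 1))
        vals = np.concatenate([v, v], axis=1)
        r2, p = cross_session_correlation(make_panel(vals), "p0", "pearson")
        assert r2 == pytest.approx(1.0)

    def test_negated_session(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(10, 1, 1))
        vals = np.concatenate([v, -v], axis=1)
        rho, p = cross_session_correlation(make_panel(vals), "p0", "spearman")
        assert rho == pytest.approx(-1.0)

    def test_spearman_matches_rank_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(15, 2, 1))
        rho, _ = cross_session_correlation(make_panel(vals), "p0", "spearman")
        # brute-force rank correlation
        a = vals[:, 0, 0]
        b = vals[:, 1, 0]
        ra = np.argsort(np.argsort(a)).astype(float)
        rb = np.argsort(np.argsort(b)).astype(float)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_flagged(self):
        vals = np.zeros((5, 2, 1))
        with pytest.raises(ValueError, match="constant"):
            cross_session_correlation(make_panel(vals), "p0")

    def test_too_few_subjects(self):
        vals = np.random.default_rng(0).normal(size=(2, 2, 1))
        with pytest.raises(ValueError):
            cross_session_correlation(make_panel(vals), "p0")


class TestParameterAnova:
    def test_matches_r_aov_oracle(self):
        """Frozen oracle: R aov with Error(subject/(session*parameter))
        on the same generated fixture (3+4 subjects, 2 sessions, 3 params)."""
        rng = np.random.default_rng(42)
        rows = []
        roster = [("s1", "g1"), ("s2", "g1"), ("s3", "g1"),
                  ("s4", "g2"), ("s5", "g2"), ("s6", "g2"), ("s7", "g2")]
        for subj, grp in roster:
            base = rng.normal(0, 0.3)
            for sess in ("A", "B"):
                for k, par in enumerate(("p1", "p2", "p3")):
                    val = (base + 0.4 * k + (0.3 if grp == "g2" else 0)
                           + (0.2 if sess == "B" else 0) + rng.normal(0, 0.25))
                    rows.append((subj, grp, sess, par, round(val, 6)))
        panel = ParamPanel(pd.DataFrame(
            rows, columns=["subject", "group", "session", "parameter", "value"]))
        res = parameter_anova(panel)
        expected = {  # F values printed by R aov
            "group": (5.57336, 1, 5),
            "session": (5.74148, 1, 5),
            "group:session": (0.02972, 1, 5),
            "connection": (64.97977, 2, 10),
            "group:connection": (1.19453, 2, 10),
            "session:connection": (1.22880, 2, 10),
            "group:session:connection": (1.20135, 2, 10),
        }
        for effect, (F, df1, df2) in expected.items():
            row = res.loc[effect]
            assert row["F"] == pytest.approx(F, abs=2e-4), effect
            assert (row["df1"], row["df2"]) == (df1, df2), effect

    def test_identical_values_give_zero_f(self):
        vals = np.ones((6, 2, 3))
        res = parameter_anova(make_panel(vals, groups=["g1"] * 3 + ["g2"] * 3))
        assert np.allclose(res["F"], 0.0)

    def test_injected_connection_effect_detected(self):
        rng = np.random.default_rng(5)
        n = 15
        vals = rng.normal(0, 0.05, size=(n, 2, 4))
        vals[:, :, 2] += 0.2  # one connection systematically higher
        res = parameter_anova(make_panel(vals, groups=["g1"] * 8 + ["g2"] * 7))
        assert res.loc["connection", "p"] < 1e-6
        assert res.loc["group", "p"] > 0.05
        assert res.loc["session", "p"] > 0.05

    def test_permuted_labels_abolish_effect(self):
        rng = np.random.default_rng(6)
        n = 12
        vals = rng.normal(0, 0.05, size=(n, 2, 3))
        vals[:, :, 1] += 0.3
        ps = []
        for rep in range(20):
            perm = vals.copy()
            for i in range(n):  # permute connection labels within subject
                for j in range(2):
                    perm[i, j] = rng.permutation(perm[i, j])
            res = parameter_anova(make_panel(perm, groups=["g1"] * 6 + ["g2"] * 6))
            ps.append(res.loc["connection", "p"])
        # permutation p values should be spread out, not concentrated at 0
        assert np.mean(np.array(ps) < 0.05) < 0.5

    def test_unbalanced_rejected(self):
        vals = np.random.default_rng(0).normal(size=(6, 2, 2))
        panel = make_panel(vals, groups=["g1"] * 3 + ["g2"] * 3)
        trimmed = ParamPanel(panel.data.iloc[:-1])
        with pytest.raises(ValueError, match="unbalanced"):
            parameter_anova(trimmed)

    def test_greenhouse_geisser_is_conservative(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(10, 2, 4))
        vals[:, :, 0] += 0.8  # real connection effect so F > 1
        panel = make_panel(vals, groups=["g1"] * 5 + ["g2"] * 5)
        plain = parameter_anova(panel)
        gg = parameter_anova(panel, correction="gg")
        assert 1.0 / 3 <= gg.loc["connection", "eps"] <= 1.0
        assert gg.loc["connection", "F"] == pytest.approx(plain.loc["connection", "F"])
        assert gg.loc["connection", "p"] >= plain.loc["connection", "p"] - 1e-12


class TestSubjectRelabelingInvariance:
    def test_statistics_invariant(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(10, 2, 2))
        panel = make_panel(vals)
        perm = rng.permutation(10)
        panel2 = make_panel(vals[perm])
        for parameter in ("p0", "p1"):
            a = cross_session_correlation(panel, parameter, "spearman")
            b = cross_session_correlation(panel2, parameter, "spearman")
            assert a == pytest.approx(b)


class TestPosteriorCorrSummary:
    def test_identity_matrices(self):
        mats = [np.eye(5)] * 4
        s = posterior_corr_group_summary(mats)
        iu = np.triu_indices(5, 1)
        assert np.allclose(s["mean"][iu], 0.0)
        assert not s["bonferroni_mask"].any()
        assert s["n_unique"] == 10

    def test_13x13_has_78_unique_elements(self):
        mats = np.tile(np.eye(13), (3, 1, 1))
        s = posterior_corr_group_summary(mats)
        assert s["n_unique"] == 78
        assert s["bonferroni_threshold"] == pytest.approx(0.05 / 78)

    def test_constant_shift_all_significant(self):
        rng = np.random.default_rng(9)
        mats = []
        for _ in range(15):
            m = np.eye(6)
            iu = np.triu_indices(6, 1)
            vals = 0.2 + rng.normal(0, 0.02, iu[0].size)
            m[iu] = vals
            m.T[iu] = vals
            mats.append(m)
        s = posterior_corr_group_summary(mats)
        iu = np.triu_indices(6, 1)
        assert s["bonferroni_mask"][iu].all()
        assert s["fraction_negative"] == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            posterior_corr_group_summary([np.eye(3)])  # only one subject
        with pytest.raises(ValueError):
            posterior_corr_group_summary(np.ones((3, 4, 5)))


class TestMatrixSessionAgreement:
    def test_identical(self):
        m = np.random.default_rng(0).normal(size=(6, 6))
        m = (m + m.T) / 2
        assert matrix_session_agreement(m, m) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(1)
        rhos = []
        for _ in range(30):
            a = rng.normal(size=(8, 8))
            b = rng.normal(size=(8, 8))
            rhos.append(matrix_session_agreement(a, b))
        # null distribution: centred on zero, modest spread
        assert abs(np.mean(rhos)) < 0.15
        assert np.percentile(np.abs(rhos), 90) < 0.5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            matrix_session_agreement(np.eye(3), np.eye(4))


def test_b_over_a_ratio_guard():
    assert b_over_a_ratio(0.06, 0.3) == pytest.approx(0.2)
    assert np.isnan(b_over_a_ratio(0.06, 1e-9))


def test_ks_normality():
    rng = np.random.default_rng(10)
    z, p = ks_normality(rng.normal(size=62))
    assert p > 0.05
    z2, p2 = ks_normality(rng.exponential(size=200))
    assert p2 < 0.05
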