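import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import exact_moments_vector
from pam.cohort_io import FeatureMatrix, log2_transform
from pam.discovery_stats import (bh_fdr, exact_wilcoxon_paired,
                                 make_ratio_features,
                                 outlier_sensitivity_retest, pareto_scale,
                                 pca_hotelling_exclude, rank_concordance,
                                 run_discovery, two_group_tests)
from pam.errors import ConfigError, QcError, StateError, ValidationError
from pam.match_controls import MatchSet


# ---------------------------------------------------------------------------
# Pareto scaling and Hotelling T2


class TestParetoScale:
    def test_zero_variance_feature_dropped(self):
        df = pd.DataFrame({"A": [1.0, 1.0, 1.0], "B": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, dropped = pareto_scale(df)
        assert dropped == ["A"] and list(scaled.columns) == ["B"]

    def test_hand_formula(self):
        # {0, 2}: mean 1, sample SD sqrt(2) -> scaled = +/- 1 / 2^(1/4)
        df = pd.DataFrame({"A": [0.0, 2.0]})
        scaled, _ = pareto_scale(df)
        expected = 1.0 / 2.0 ** 0.25
        np.testing.assert_allclose(scaled["A"].to_numpy(),
                                   [-expected, expected], rtol=1e-12)

    def test_requires_log_state(self, raw_matrix):
        with pytest.raises(StateError):
            pareto_scale(raw_matrix)

    def test_all_zero_variance_is_qc_error(self):
        with pytest.raises(QcError):
            pareto_scale(pd.DataFrame({"A": [2.0, 2.0]}))


class TestHotelling:
    def test_planted_outlier_excluded(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(51, 30))
        X[50, :10] += 20.0
        df = pd.DataFrame(X, index=[f"S{i}" for i in range(51)])
        scaled, _ = pareto_scale(df)
        result = pca_hotelling_exclude(scaled, alpha=0.001, n_components=5)
        assert result.excluded_sample_ids == ["S50"]
        assert result.t2["S50"] > result.t2_critical

    def test_single_component_closed_form(self):
        # A = 1 on one feature: T2 reduces to the squared standardized score
        x = np.array([1.0, 3.0, 4.0, 8.0, 9.0])
        df = pd.DataFrame({"A": x})
        result = pca_hotelling_exclude(df, n_components=1)
        expected = (x - x.mean()) ** 2 / x.var(ddof=1)
        np.testing.assert_allclose(result.t2.to_numpy(), expected, rtol=1e-10)

    def test_explained_fractions_non_increasing(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(40, 12)))
        result = pca_hotelling_exclude(df, n_components=5)
        fr = result.explained_variance_fractions
        assert all(a >= b for a, b in zip(fr, fr[1:]))

    def test_degenerate_input_rejected(self):
        df = pd.DataFrame(np.ones((5, 3)))
        with pytest.raises(QcError):
            pca_hotelling_exclude(df)
        with pytest.raises(ConfigError):
            pca_hotelling_exclude(df, n_components=0)


# ---------------------------------------------------------------------------
# two-group tests


class TestTwoGroupTests:
    def test_identical_groups(self):
        r = two_group_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_student == pytest.approx(1.0)
        assert r.log2_fc == 0.0

    def test_student_equals_welch_for_equal_variances_and_sizes(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = a + 0.37          # identical sample variance, equal n
        r = two_group_tests(a, b)
        assert r.p_student == pytest.approx(r.p_welch, abs=1e-12)

    def test_welch_closed_form_on_reported_moments(self):
        """Groups synthesized to the reported means/SDs (26.90 +/- 0.68,
        n=16 vs 27.61 +/- 0.48, n=32) reproduce the closed-form Welch p."""
        case = exact_moments_vector(26.90, 0.68, 16)
        ctrl = exact_moments_vector(27.61, 0.48, 32)
        r = two_group_tests(case, ctrl)
        se2 = 0.68 ** 2 / 16 + 0.48 ** 2 / 32
        t = (26.90 - 27.61) / np.sqrt(se2)
        df = se2 ** 2 / ((0.68 ** 2 / 16) ** 2 / 15 + (0.48 ** 2 / 32) ** 2 / 31)
        expected = 2 * stats.t.sf(abs(t), df)
        assert r.p_welch == pytest.approx(expected, rel=1e-10)
        assert 1e-4 < r.p_welch < 1e-2     # same order as the study's raw-data p
        assert r.log2_fc == pytest.approx(-0.71, abs=1e-12)

    def test_mwu_exact_enumeration(self):
        # {1,2} vs {100,101}: complete separation; exact two-sided p = 2/6
        r = two_group_tests([1.0, 2.0], [100.0, 101.0])
        pooled = [1.0, 2.0, 100.0, 101.0]
        count = 0
        observed_u = 0  # every case value below every control value
        for combo in itertools.combinations(range(4), 2):
            case = [pooled[i] for i in combo]
            ctrl = [pooled[i] for i in range(4) if i not in combo]
            u = sum(c > d for c in case for d in ctrl)
            if min(u, 4 - u) <= min(observed_u, 4 - observed_u):
                count += 1
        assert r.p_mwu == pytest.approx(count / 6)

    def test_mwu_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=10)
        b = rng.normal(0.8, 1.0, size=14)
        p_raw = two_group_tests(a, b).p_mwu
        p_exp = two_group_tests(np.exp(a), np.exp(b)).p_mwu
        p_cub = two_group_tests(a ** 3, b ** 3).p_mwu
        assert p_raw == pytest.approx(p_exp) == pytest.approx(p_cub)

    def test_levene_trigger_flag(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 5.0, size=20)
        b = rng.normal(0, 0.5, size=20)
        r = two_group_tests(a, b)
        assert r.p_levene < 0.1 and r.robustness_flagged
        assert r.p_levene == pytest.approx(
            stats.levene(a, b, center="median").pvalue, rel=1e-9)

    def test_degenerate_variance_gives_nan(self):
        r = two_group_tests([2.0, 2.0, 2.0], [2.0, 2.0])
        assert np.isnan(r.p_student) and np.isnan(r.p_welch)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def bh_brute_force(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, idx in enumerate(order):
        q[idx] = min(p[order[j]] * m / (j + 1) for j in range(pos, m))
    return np.minimum(q, 1.0)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.04, 0.03, 0.005]),
                                   [0.02, 0.04, 0.04, 0.02])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 10), [0.2] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.1, 1.2])

    def test_nan_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_brute_force([0.01, 0.04]))

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_brute_force(p), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(12)
        p = np.sort(rng.uniform(size=30))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-12)


# ---------------------------------------------------------------------------
# exact paired Wilcoxon


def wilcoxon_brute_force(diffs):
    """Full 2^n enumeration of sign assignments (oracle for small n)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d), method="average")
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            count += 1
    return count / 2.0 ** n


class TestExactWilcoxon:
    def test_all_negative_n6(self):
        r = exact_wilcoxon_paired([-1, -2, -3, -4, -5, -6])
        assert r.w_statistic == 0.0
        assert r.p == pytest.approx(2 / 64)

    def test_w1_n6(self):
        r = exact_wilcoxon_paired([0.5, -1, -2, -3, -4, -5])
        assert r.w_statistic == 1.0
        assert r.p == pytest.approx(0.0625)

    def test_single_difference(self):
        assert exact_wilcoxon_paired([1.5]).p == 1.0

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            r = exact_wilcoxon_paired([0.0, 0.0])
        assert r.p == 1.0 and r.n_used == 0

    @pytest.mark.parametrize("n", range(1, 11))
    def test_matches_full_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            d = np.round(rng.normal(size=n), 2)
            d = d[d != 0]
            if len(d) == 0:
                continue
            r = exact_wilcoxon_paired(d)
            assert r.p == pytest.approx(wilcoxon_brute_force(d), abs=1e-12)

    def test_agrees_with_scipy_exact_mode(self):
        rng = np.random.default_rng(15)
        d = rng.normal(size=12)  # continuous: no ties, no zeros
        ours = exact_wilcoxon_paired(d)
        ref = stats.wilcoxon(d, method="exact", alternative="two-sided")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# discovery screen, ranks, ratios, sensitivity


def _match_sets(case_ids, control_ids):
    return [MatchSet(c, list(control_ids), [0.0] * len(control_ids), 0)
            for c in case_ids]


def _toy_log_matrix(seed=0, n_case=6, n_ctrl=8, n_feat=12, shift=-2.0):
    rng = np.random.default_rng(seed)
    ids = [f"C{i}" for i in range(n_case)] + [f"N{i}" for i in range(n_ctrl)]
    data = pd.DataFrame(rng.normal(25, 0.5, size=(len(ids), n_feat)),
                        index=ids, columns=[f"F{j}" for j in range(n_feat)])
    data.iloc[:n_case, 0] += shift
    return FeatureMatrix(data, log_transformed=True), \
        [f"C{i}" for i in range(n_case)], [f"N{i}" for i in range(n_ctrl)]


class TestRunDiscovery:
    def test_spiked_feature_tops_all_ranks(self):
        matrix, case, ctrl = _toy_log_matrix()
        res = run_discovery(matrix, _match_sets(case, ctrl))
        hit = res.set_index("feature_id").loc["F0"]
        assert hit[["rank_student", "rank_welch", "rank_mwu"]].eq(1.0).all()
        assert hit["q"] < 0.05
        assert hit["log2_fc"] == pytest.approx(-2.0, abs=0.6)

    def test_overlapping_groups_rejected(self):
        matrix, case, ctrl = _toy_log_matrix()
        from pam.errors import IntegrityError
        with pytest.raises(IntegrityError):
            run_discovery(matrix, _match_sets(case, case))

    def test_requires_log_state(self, raw_matrix):
        with pytest.raises(StateError):
            run_discovery(raw_matrix, [])

    def test_scope_restricts_fdr_burden(self):
        matrix, case, ctrl = _toy_log_matrix()
        matrix.annotated[:] = [True] * 6 + [False] * 6
        res_ann = run_discovery(matrix, _match_sets(case, ctrl),
                                feature_scope="annotated_only")
        res_all = run_discovery(matrix, _match_sets(case, ctrl),
                                feature_scope="all_features")
        assert len(res_ann) == 6 and len(res_all) == 12
        # same primary p, larger multiplicity burden -> q can only grow
        p0 = res_ann.set_index("feature_id").loc["F0"]
        pa = res_all.set_index("feature_id").loc["F0"]
        assert pa["p_student"] == pytest.approx(p0["p_student"])
        assert pa["q"] >= p0["q"] - 1e-12

    def test_q_never_below_primary_p(self):
        matrix, case, ctrl = _toy_log_matrix(seed=7)
        res = run_discovery(matrix, _match_sets(case, ctrl))
        assert (res["q"] >= res["p_student"] - 1e-12).all()
        # minimum-rank convention: rank = 1 + number of strictly smaller p
        for test in ("student", "welch", "mwu"):
            p = res[f"p_{test}"].to_numpy()
            expected = 1 + (p[:, None] > p[None, :]).sum(axis=1)
            np.testing.assert_array_equal(res[f"rank_{test}"].to_numpy(),
                                          expected)


class TestRankConcordance:
    def _frame(self, ranks):
        df = pd.DataFrame(ranks, columns=["rank_student", "rank_welch",
                                          "rank_mwu"])
        df["feature_id"] = [f"F{i}" for i in range(len(df))]
        return df

    def test_single_feature(self):
        out = rank_concordance(self._frame([[1, 1, 1]]))
        assert out.loc[0, "min_rank"] == out.loc[0, "max_rank"] == 1
        assert bool(out.loc[0, "all_tests_top_1"])

    def test_disagreement_detected(self):
        out = rank_concordance(self._frame([[1, 1, 2], [2, 2, 1]]))
        assert out.loc[0, "min_rank"] == 1 and out.loc[0, "max_rank"] == 2
        assert not out["all_tests_top_1"].any()

    def test_anticorrelated_ranks_spread(self):
        m = 20
        ranks = [[i + 1, m - i, i + 1] for i in range(m)]
        out = rank_concordance(self._frame(ranks))
        assert (out["max_rank"] - out["min_rank"]).max() == m - 1


class TestRatios:
    def test_identical_members_give_zero(self):
        m, *_ = _toy_log_matrix()
        vals = make_ratio_features(m, {"R": ("F1", "F1")})
        assert (vals["R"] == 0).all()

    def test_log2_ratio_from_raw_values(self):
        raw = FeatureMatrix(pd.DataFrame({"A": [8.0], "B": [2.0]}, index=["S1"]))
        vals = make_ratio_features(log2_transform(raw), {"A/B": ("A", "B")})
        assert vals.loc["S1", "A/B"] == pytest.approx(2.0)

    def test_unknown_member_rejected(self):
        m, *_ = _toy_log_matrix()
        with pytest.raises(ConfigError, match="ZZ"):
            make_ratio_features(m, {"R": ("F0", "ZZ")})

    def test_ratio_variance_is_sum_of_member_variances(self):
        rng = np.random.default_rng(30)
        n = 4000
        a = rng.normal(25, 0.5, size=n)
        b = rng.normal(24, 0.4, size=n)
        data = pd.DataFrame({"A": a, "B": b},
                            index=[f"S{i}" for i in range(n)])
        m = FeatureMatrix(data, log_transformed=True)
        vals = make_ratio_features(m, {"A/B": ("A", "B")})
        assert vals["A/B"].var() == pytest.approx(0.5 ** 2 + 0.4 ** 2, rel=0.1)


class TestOutlierRetest:
    def test_empty_rules_identity(self):
        vals = {"W24_48": ([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])}
        out = outlier_sensitivity_retest(vals, {})
        before = out[out["phase"] == "before"].drop(columns="phase")
        after = out[out["phase"] == "after"].drop(columns="phase")
        pd.testing.assert_frame_equal(before.reset_index(drop=True),
                                      after.reset_index(drop=True))

    def test_dropping_planted_outlier_restores_homoscedasticity(self):
        rng = np.random.default_rng(4)
        case = np.r_[rng.normal(24, 0.3, 20), 22.5]   # one extreme low value
        ctrl = rng.normal(25, 0.3, 40)
        out = outlier_sensitivity_retest({"W24_48": (case, ctrl)},
                                         {"W24_48": ("min", "case")})
        before = out[out["phase"] == "before"].iloc[0]
        after = out[out["phase"] == "after"].iloc[0]
        assert before["p_levene"] < 0.1 < after["p_levene"]
        assert after["n_case"] == 20

    def test_dropping_mean_value_barely_moves_effect(self):
        case = np.array([24.0, 25.0, 26.0, 25.0])
        ctrl = np.array([26.0, 27.0, 28.0])
        out = outlier_sensitivity_retest(
            {"W": (np.r_[case, case.mean()], ctrl)}, {"W": ("max", "control")})
        fc = out.set_index("phase")["log2_fc"]
        assert abs(fc["after"] - fc["before"]) < 1.0

    def test_too_small_group_skips_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = outlier_sensitivity_retest(
                {"W": ([1.0, 2.0], [3.0, 4.0, 5.0])}, {"W": ("min", "case")})
        assert (out["phase"] == "after").sum() == 0
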