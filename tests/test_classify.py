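import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from effbias import (
    FeatureTable,
    ValidationError,
    bh_adjust,
    classify_all,
    classify_metabolite,
    differential_test,
)


def _two_group_table(a_vals, b_vals, mets=("M1",)):
    """Control/challenge table from per-metabolite value arrays."""
    a_vals, b_vals = np.atleast_2d(a_vals), np.atleast_2d(b_vals)
    if a_vals.shape[0] == 1 and len(mets) == 1:
        a_vals, b_vals = a_vals.T, b_vals.T
    n_a, n_b = a_vals.shape[0], b_vals.shape[0]
    ids = [f"c{i}" for i in range(n_a)] + [f"x{i}" for i in range(n_b)]
    groups = pd.Series(["control"] * n_a + ["challenge"] * n_b, index=ids)
    values = pd.DataFrame(np.vstack([a_vals, b_vals]), index=ids, columns=list(mets))
    return FeatureTable(values=values, groups=groups)


def _bh_oracle(p):
    """Hand-executable BH step-up: p_(i) * m / i, cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestDifferentialTest:
    def test_identical_groups_with_spread_give_t_zero_p_one(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        table = _two_group_table(vals, vals)
        res = differential_test(table, "control", "challenge", method="t")
        assert res.loc["M1", "statistic"] == 0.0
        assert res.loc["M1", "p"] == 1.0

    def test_constant_identical_groups_flagged_degenerate(self):
        table = _two_group_table(np.ones(4), np.ones(4))
        res = differential_test(table, "control", "challenge")
        assert bool(res.loc["M1", "degenerate"])
        assert res.loc["M1", "p"] == 1.0

    def test_too_small_group_rejected(self):
        table = _two_group_table(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError, match="fewer than 3"):
            differential_test(table, "control", "challenge")

    def test_auto_picks_mannwhitney_for_skewed_data(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(0, 2, size=40)) ** 3  # heavily skewed
        b = np.exp(rng.normal(0.2, 2, size=40)) ** 3
        table = _two_group_table(a, b)
        res = differential_test(table, "control", "challenge", method="auto")
        assert res.loc["M1", "method"] == "mannwhitney"

    def test_vectorized_path_matches_per_column_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 5))
        b = rng.normal(0.5, 1, size=(8, 5))
        mets = [f"M{j}" for j in range(5)]
        table = _two_group_table(np.abs(a) + 1, np.abs(b) + 1, mets=mets)
        res = differential_test(table, "control", "challenge", method="t")
        for j, met in enumerate(mets):
            ref = stats.ttest_ind(np.abs(a[:, j]) + 1, np.abs(b[:, j]) + 1)
            assert res.loc[met, "p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_missing_values_dropped_per_metabolite(self):
        a = np.array([1.0, 2.0, 3.0, np.nan])
        b = np.array([4.0, 5.0, 6.0, 7.0])
        table = _two_group_table(a, b)
        res = differential_test(table, "control", "challenge", method="t")
        assert np.isfinite(res.loc["M1", "p"])

    def test_bh_example_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_bh_fixed_point_all_equal(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=30))
    def test_bh_matches_hand_oracle(self, p):
        assert np.allclose(bh_adjust(p), _bh_oracle(p))


class TestClassifyMetabolite:
    @pytest.mark.parametrize(
        "m_c, m_a, m_t, sig, expected",
        [
            (0.0, 2.0, 1.0, True, "efficacy"),
            (0.0, 2.0, 3.0, True, "bias_up"),
            (0.0, 2.0, -1.0, True, "bias_down"),
            (0.0, 2.0, 1.0, False, "unclassified"),
            (0.0, 2.0, 3.0, False, "bias_up"),  # bias needs no challenge effect
            (1.0, 1.0, 1.0, False, "unclassified"),  # degenerate interval
            (2.0, 0.0, 1.0, True, "efficacy"),  # symmetric in control/challenge
        ],
    )
    def test_rule_on_examples(self, m_c, m_a, m_t, sig, expected):
        assert classify_metabolite(m_c, m_a, m_t, challenge_significant=sig) == expected

    def test_epsilon_shrinks_between_interval(self):
        assert classify_metabolite(0, 2, 0.05, True, epsilon=0.1) == "unclassified"
        assert classify_metabolite(0, 2, 2.05, True, epsilon=0.1) == "unclassified"
        assert classify_metabolite(0, 2, 2.2, True, epsilon=0.1) == "bias_up"

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(-5, 5), st.floats(-5, 5), st.floats(-5, 5),
        st.booleans(), st.floats(0, 0.5),
    )
    def test_symmetric_in_control_and_challenge(self, m_c, m_a, m_t, sig, eps):
        assert classify_metabolite(m_c, m_a, m_t, sig, eps) == classify_metabolite(
            m_a, m_c, m_t, sig, eps
        )

    def test_nonfinite_mean_rejected(self):
        with pytest.raises(ValidationError, match="finite"):
            classify_metabolite(np.nan, 1.0, 1.0, True)


def _verdict_inputs(table):
    """VIP/diff frames granting every metabolite gate passage."""
    mets = table.metabolite_ids
    vip = pd.DataFrame({"vip": np.full(len(mets), 2.0)}, index=pd.Index(mets))
    sig = pd.DataFrame(
        {"statistic": 0.0, "p": 1e-4, "p_adj": 1e-4, "method": "t", "degenerate": False},
        index=pd.Index(mets),
    )
    return vip, sig


class TestClassifyAll:
    def _four_group_table(self, seed=0, n=5, n_met=6):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["control", "challenge", "treated", "drug_alone"], n)
        ids = [f"s{i}" for i in range(4 * n)]
        values = pd.DataFrame(
            rng.normal(size=(4 * n, n_met)),
            index=ids, columns=[f"M{j}" for j in range(n_met)],
        )
        return FeatureTable(values=values, groups=pd.Series(groups, index=ids))

    def test_low_vip_is_always_unclassified(self):
        table = self._four_group_table()
        vip, sig = _verdict_inputs(table)
        vip.loc["M0", "vip"] = 0.5
        verdicts = classify_all(table, vip, sig, sig)
        assert verdicts.loc["M0", "class"] == "unclassified"

    def test_id_mismatch_lists_missing(self):
        table = self._four_group_table()
        vip, sig = _verdict_inputs(table)
        with pytest.raises(ValidationError, match="M5"):
            classify_all(table, vip.drop(index="M5"), sig, sig)

    def test_matches_scalar_rule_with_gates(self, planted_cohort, fast_config):
        """Vectorized verdicts equal a metabolite-by-metabolite application
        of the scalar rule plus the two significance gates."""
        from effbias import compute_vip, fit_plsda, preprocess

        table, _, _ = planted_cohort
        pre = preprocess(table)
        model = fit_plsda(pre.X, pre.groups)
        vip = compute_vip(model, pre.metabolite_ids)
        at = pre.analysis_table
        dc = differential_test(at, "control", "challenge")
        dt = differential_test(at, "control", "treated")
        verdicts = classify_all(at, vip, dc, dt)
        means = at.group_means()
        for met in at.metabolite_ids:
            if vip.loc[met, "vip"] <= 1.0:
                expected = "unclassified"
            else:
                expected = classify_metabolite(
                    means.at[met, "control"], means.at[met, "challenge"],
                    means.at[met, "treated"],
                    challenge_significant=dc.loc[met, "p_adj"] < 0.05,
                )
                if expected in ("bias_up", "bias_down") and not dt.loc[met, "p_adj"] < 0.05:
                    expected = "unclassified"
            assert verdicts.loc[met, "class"] == expected

    def test_classes_partition_the_table(self, planted_cohort):
        from effbias import compute_vip, fit_plsda, preprocess

        table, _, _ = planted_cohort
        pre = preprocess(table)
        vip = compute_vip(fit_plsda(pre.X, pre.groups), pre.metabolite_ids)
        at = pre.analysis_table
        dc = differential_test(at, "control", "challenge")
        dt = differential_test(at, "control", "treated")
        verdicts = classify_all(at, vip, dc, dt)
        counts = verdicts["class"].value_counts()
        assert counts.sum() == len(at.metabolite_ids)
        assert set(counts.index) <= {"efficacy", "bias_up", "bias_down", "unclassified"}

    def test_recovered_bias_count_monotone_in_bias_effect(self):
        """Mean recovered bias count never decreases along a bias-effect grid."""
        from effbias import (
            CohortSpec,
            compute_vip,
            fit_plsda,
            generate_cohort,
            preprocess,
        )

        reps = 20
        mean_counts = []
        for effect in (0.0, 1.5, 3.0):
            total = 0
            for r in range(reps):
                spec = CohortSpec(
                    n_metabolites=120, n_efficacy=0, n_bias=15,
                    challenge_effect=0.0, bias_effect=effect, seed=1000 + r,
                )
                table, truth = generate_cohort(spec)
                pre = preprocess(table)
                vip = compute_vip(fit_plsda(pre.X, pre.groups), pre.metabolite_ids)
                at = pre.analysis_table
                dc = differential_test(at, "control", "challenge")
                dt = differential_test(at, "control", "treated")
                verdicts = classify_all(at, vip, dc, dt)
                called = verdicts["class"].isin(["bias_up", "bias_down"])
                total += int((called & verdicts.index.isin(truth.bias_ids)).sum())
            mean_counts.append(total / reps)
        assert mean_counts[0] <= mean_counts[1] <= mean_counts[2]
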