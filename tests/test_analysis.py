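"""Analysis-pipeline tests with brute-force oracles for the rank statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mlpgg.analysis import (
    AnalysisError,
    action_trend_model,
    first_round_logistic,
    group_summaries,
    holm_bonferroni,
    identity_models,
    linear_combination_test,
    mann_whitney,
    run_preregistered_suite,
    wilcoxon_signed_rank,
)
from mlpgg.simulate import IdentityDynamics, SimConfig, generate_dataset


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_u(a, b):
    """U statistic for sample a: count of (a_i, b_j) pairs with a_i > b_j,
    ties counted half."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_force_w_minus(d):
    """Signed-rank W-minus by direct midrank computation."""
    d = [x for x in d if x != 0]
    ranks = {}
    order = sorted(range(len(d)), key=lambda i: abs(d[i]))
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and abs(d[order[j]]) == abs(d[order[i]]):
            j += 1
        midrank = (i + 1 + j) / 2
        for k in range(i, j):
            ranks[order[k]] = midrank
        i = j
    return sum(r for i, r in ranks.items() if d[i] < 0)


def exact_mw_p(a, b):
    """Two-sided p by full enumeration of group assignments (tie-free)."""
    pooled = list(a) + list(b)
    observed = brute_force_u(a, b)
    n_a = len(a)
    mean_u = n_a * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        aa = [pooled[i] for i in combo]
        bb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = brute_force_u(aa, bb)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Rank tests


class TestMannWhitney:
    def test_separated_samples_have_zero_u(self):
        res = mann_whitney([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        assert res.statistic == 0.0

    def test_identical_multisets_give_p_near_one(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_raw > 0.9

    def test_shift_invariance(self):
        a, b = [0.1, 0.5, 0.9, 0.3], [0.2, 0.6, 0.4]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney([x + 17.3 for x in a], [x + 17.3 for x in b])
        assert r1.statistic == r2.statistic and r1.p_raw == r2.p_raw

    def test_empty_side_rejected(self):
        with pytest.raises(AnalysisError):
            mann_whitney([], [1.0])

    @settings(max_examples=120, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 8).map(float), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 8).map(float), min_size=1, max_size=8),
    )
    def test_statistic_matches_brute_force(self, a, b):
        assert mann_whitney(a, b).statistic == pytest.approx(brute_force_u(a, b))

    @pytest.mark.parametrize(
        "a, b",
        [
            ([1.0, 4.0, 6.0], [2.0, 3.0, 5.0]),
            ([1.0, 2.0], [3.0, 4.0, 5.0]),
            ([10.0, 30.0, 50.0, 70.0], [20.0, 40.0, 60.0]),
        ],
    )
    def test_exact_p_matches_enumeration(self, a, b):
        assert mann_whitney(a, b).p_raw == pytest.approx(exact_mw_p(a, b))


class TestWilcoxon:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0  # W-minus

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(AnalysisError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_sign_flip_antisymmetry(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 2.0, 3.0, 2.5, 4.0]
        r1 = wilcoxon_signed_rank(x, y)
        r2 = wilcoxon_signed_rank(y, x)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    @settings(max_examples=120, derandomize=True)
    @given(
        d=st.lists(st.integers(-6, 6).map(float), min_size=1, max_size=8).filter(
            lambda d: any(x != 0 for x in d)
        )
    )
    def test_statistic_matches_brute_force(self, d):
        x = [10.0 + v for v in d]
        y = [10.0] * len(d)
        assert wilcoxon_signed_rank(x, y).statistic == pytest.approx(brute_force_w_minus(d))


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.037]) == [0.037]

    def test_hand_worked_example(self):
        assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    @settings(max_examples=100, derandomize=True)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_adjusted_dominates_raw_and_capped(self, p):
        adj = holm_bonferroni(p)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)

    @settings(max_examples=60, derandomize=True)
    @given(p=st.lists(st.floats(0, 1), min_size=2, max_size=8), seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, p, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        adj = holm_bonferroni(p)
        adj_perm = holm_bonferroni([p[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(AnalysisError):
            holm_bonferroni([0.5, 1.2])


# ---------------------------------------------------------------------------
# Descriptives


class TestGroupSummaries:
    def test_degenerate_all_keep_group(self):
        rows = []
        for rnd in (1, 2):
            for pid in range(6):
                rows.append(
                    dict(group_id="g", condition="balanced", round=rnd,
                         player_id=f"p{pid}", subgroup=1 + pid // 3, action="keep",
                         global_pot=0, local_pot_1=0, local_pot_2=0, kept=6,
                         global_met=False, local1_met=False, local2_met=False, payoff=1.0)
                )
        s = group_summaries(pd.DataFrame(rows))
        assert s.loc[0, "prop_keep"] == 1.0
        assert s.loc[0, "prop_global"] == 0.0
        assert s.loc[0, "global_success_rate"] == 0.0

    def test_proportions_sum_to_one(self, small_dataset):
        s = group_summaries(small_dataset.actions)
        totals = s[["prop_global", "prop_own_local", "prop_other_local", "prop_keep"]].sum(axis=1)
        assert np.allclose(totals, 1.0)

    def test_success_rates_match_flag_means(self, small_dataset):
        s = group_summaries(small_dataset.actions).set_index("group_id")
        a = small_dataset.actions
        g0 = a["group_id"].iloc[0]
        g = a[a["group_id"] == g0]
        expected = g.groupby("round")["global_met"].first().mean()
        assert s.loc[g0, "global_success_rate"] == pytest.approx(expected)

    def test_missing_columns_named(self):
        with pytest.raises(AnalysisError, match="action"):
            group_summaries(pd.DataFrame({"group_id": [], "condition": []}))


# ---------------------------------------------------------------------------
# Regressions


class TestTrendModel:
    def test_strong_defection_drift_recovered_as_positive_trend(self):
        from mlpgg.simulate import AgentParams
        import dataclasses

        ap = dataclasses.replace(AgentParams(), invest_round_drift=-0.25)
        ds = generate_dataset(SimConfig(n_groups_per_condition=10, seed=5, agent_params=ap))
        fit = action_trend_model(ds.actions, "keep")
        assert fit.params["round"] > 0
        assert fit.pvalues["round"] < 0.01

    def test_round_shuffle_centres_trend_at_zero(self, small_dataset):
        """Permuting round labels within groups destroys the trend."""
        rng = np.random.default_rng(0)
        coefs = []
        base = small_dataset.actions
        for _ in range(12):
            shuffled = base.copy()
            new_rounds = shuffled.groupby(["group_id", "player_id"])["round"].transform(
                lambda s: rng.permutation(s.to_numpy())
            )
            shuffled["round"] = new_rounds
            coefs.append(action_trend_model(shuffled, "keep").params["round"])
        observed = action_trend_model(base, "keep").params["round"]
        coefs = np.array(coefs)
        assert abs(coefs.mean()) < max(3 * coefs.std(ddof=1) / math.sqrt(len(coefs)), 1e-3)
        assert observed > coefs.max()

    def test_constant_outcome_flagged_degenerate(self, small_dataset):
        df = small_dataset.actions.copy()
        df["action"] = "keep"
        with pytest.raises(AnalysisError, match="constant"):
            action_trend_model(df, "keep")


class TestLinearCombination:
    def test_identity_weights_reproduce_single_coefficient(self, small_dataset):
        fit = action_trend_model(small_dataset.actions, "keep")
        res = linear_combination_test(fit, {"round": 1.0})
        assert res.estimate == pytest.approx(fit.params["round"])
        assert res.p_raw == pytest.approx(fit.pvalues["round"], rel=1e-6)

    def test_zero_weights(self, small_dataset):
        fit = action_trend_model(small_dataset.actions, "keep")
        res = linear_combination_test(fit, {"round": 0.0})
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_agrees_with_reparameterised_refit(self, small_dataset):
        """The Wald contrast for round + round:boost equals the round slope
        of a model refitted with the boost condition as reference."""
        local = small_dataset.actions[
            small_dataset.actions["condition"].isin(["balanced", "global_boost"])
        ]
        fit = action_trend_model(local, "invest_own_local", reference="balanced")
        contrast = linear_combination_test(
            fit, {"round": 1.0, "round:cond[global_boost]": 1.0}
        )
        refit = action_trend_model(local, "invest_own_local", reference="global_boost")
        assert contrast.estimate == pytest.approx(refit.params["round"], rel=1e-5)

    def test_unknown_weight_rejected(self, small_dataset):
        fit = action_trend_model(small_dataset.actions, "keep")
        with pytest.raises(AnalysisError):
            linear_combination_test(fit, {"nonexistent": 1.0})


class TestFirstRoundLogistic:
    def test_recovers_identity_slope_on_one_seed(self):
        ds = generate_dataset(SimConfig(n_groups_per_condition=57, seed=8))
        fit = first_round_logistic(ds.actions, ds.identity)
        lo, hi = fit.conf_int["identity_diff"]
        assert lo < 0.03 < hi

    def test_constant_difference_flagged(self, small_dataset):
        iden = small_dataset.identity.copy()
        iden["score_global"] = iden["score_own_local"]
        with pytest.raises(AnalysisError, match="constant"):
            first_round_logistic(small_dataset.actions, iden)

    def test_label_swap_negates_coefficient(self, small_dataset):
        fit = first_round_logistic(small_dataset.actions, small_dataset.identity)
        swapped = small_dataset.identity.rename(
            columns={"score_global": "score_own_local", "score_own_local": "score_global"}
        )
        fit_swapped = first_round_logistic(small_dataset.actions, swapped)
        assert fit_swapped.params["identity_diff"] == pytest.approx(
            -fit.params["identity_diff"], rel=1e-4
        )


class TestIdentityModels:
    def test_zero_drift_zero_boost_centres_at_zero(self):
        from mlpgg.simulate import InitialIdentityDistribution

        dynamics = IdentityDynamics(
            drift_global=0.0, drift_own_local=0.0, drift_other_local=0.0,
            boost_global=0.0, boost_local=0.0,
        )
        # mid-scale starting scores keep the null random walk away from the
        # clipping bounds, so the estimates are centred rather than censored
        mid = InitialIdentityDistribution(
            params={"own_local": (50.0, 10.0), "other_local": (50.0, 10.0), "global": (50.0, 10.0)}
        )
        ds = generate_dataset(
            SimConfig(
                n_groups_per_condition=12, seed=13, identity_dynamics=dynamics,
                initial_identity={c: mid for c in ("global_only", "balanced", "global_boost")},
            )
        )
        level, change = identity_models(ds.identity, ds.actions, scale="global")
        lo, hi = change.conf_int["successes"]
        assert lo < 0.0 < hi
        lo, hi = change.conf_int["const"]
        assert lo < 0.0 < hi

    def test_recovers_drift_and_boost_on_one_seed(self):
        ds = generate_dataset(SimConfig(n_groups_per_condition=57, seed=17))
        _, change = identity_models(ds.identity, ds.actions, scale="global")
        lo, hi = change.conf_int["const"]
        assert lo < -0.76 < hi
        lo, hi = change.conf_int["successes"]
        assert lo < 2.09 < hi

    def test_single_wave_rejected(self, small_dataset):
        iden = small_dataset.identity
        with pytest.raises(AnalysisError):
            identity_models(iden[iden["wave"] == 0], small_dataset.actions)


class TestPreregisteredSuite:
    def test_one_entry_per_hypothesis(self, small_dataset):
        report = run_preregistered_suite(small_dataset.actions, small_dataset.identity)
        expected = {
            "H1a", "H1b", "H2a", "H2b", "H3a", "H3b", "H3c", "H3c_boost_contrast",
            "H4a", "H4b", "H5", "H6_global", "H7_global", "H6_own_local", "H7_own_local",
        }
        assert expected <= set(report["hypotheses"])
        for hid in expected:
            assert "error" not in report["hypotheses"][hid], (
                hid, report["hypotheses"][hid])

    def test_deterministic(self, small_dataset):
        r1 = run_preregistered_suite(small_dataset.actions, small_dataset.identity)
        r2 = run_preregistered_suite(small_dataset.actions, small_dataset.identity)
        assert r1 == r2

    def test_adjusted_p_dominates_raw(self, small_dataset):
        report = run_preregistered_suite(small_dataset.actions, small_dataset.identity)
        for hid in ("H1a", "H1b", "H2a", "H2b"):
            h = report["hypotheses"][hid]
            assert h["p_adjusted"] >= h["p_raw"]

    def test_paper_sign_pattern_on_defaults(self):
        """Majority-of-seeds check of the headline directions: the local
        option lowers global cooperation (H1a), the boost raises it (H2a),
        global cooperation falls over rounds (H3a) and defection rises
        (H3b)."""
        votes = {"H1a": 0, "H2a": 0, "H3a": 0, "H3b": 0}
        seeds = (101, 202, 303)
        for seed in seeds:
            ds = generate_dataset(SimConfig(n_groups_per_condition=20, seed=seed))
            rep = run_preregistered_suite(ds.actions, ds.identity)["hypotheses"]
            votes["H1a"] += rep["H1a"]["estimate"] > 0  # global_only minus balanced
            votes["H2a"] += rep["H2a"]["estimate"] > 0  # boost minus balanced
            votes["H3a"] += rep["H3a"]["params"]["round"] < 0
            votes["H3b"] += rep["H3b"]["params"]["round"] > 0
        for hid, v in votes.items():
            assert v >= 2, (hid, votes)
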