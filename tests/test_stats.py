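"""Statistics battery: rank tests, Holm ladder, correlations, stepwise."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from armkin.stats import (
    classify_correlation,
    correlate_and_classify,
    forward_stepwise_regression,
    holm_bonferroni,
    kruskal_wallis,
    mann_whitney,
    run_group_comparison,
)
from armkin.simulate import SimulationConfig, simulate_clinical_cohort


def _kw_oracle(*groups):
    """Rank-formula Kruskal-Wallis H (no ties), independent of scipy."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    n = len(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def _mwu_exact_p(a, b):
    """Exhaustive enumeration of rank assignments (tie-free, two-sided)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_min(sample_a, sample_b):
        u_a = sum((x > y) for x in sample_a for y in sample_b)
        return min(u_a, len(sample_a) * len(sample_b) - u_a)

    observed = u_min(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        if u_min(pooled[sel], pooled[~sel]) <= observed:
            count += 1
        total += 1
    return count / total


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        H, p = kruskal_wallis([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_match_rank_formula_oracle(self):
        g = ([1, 2, 3], [4, 5, 6], [7, 8, 9])
        H, p = kruskal_wallis(*g)
        assert H == pytest.approx(_kw_oracle(*g), abs=1e-9)
        assert H == pytest.approx(7.2, abs=1e-9)

    def test_random_tie_free_samples_match_oracle(self, rng):
        for _ in range(20):
            g = [rng.permutation(30)[: rng.integers(3, 8)] + rng.normal(0, 1e-6)
                 for _ in range(3)]
            H, _ = kruskal_wallis(*g)
            assert H == pytest.approx(_kw_oracle(*g), abs=1e-8)

    def test_all_constant_reports_h0_p1(self):
        assert kruskal_wallis([5, 5], [5, 5], [5]) == (0.0, 1.0)

    def test_small_sample_p_close_to_permutation_null(self, rng):
        # p from the chi-square reference vs a permutation estimate
        a, b, c = [1.0, 6.0, 7.0], [2.0, 4.0, 9.0], [3.0, 5.0, 8.0]
        H_obs, p = kruskal_wallis(a, b, c)
        pooled = np.array(a + b + c)
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _kw_oracle(perm[:3], perm[3:6], perm[6:]) >= H_obs - 1e-9:
                count += 1
        assert p == pytest.approx(count / n_perm, abs=0.08)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0

    def test_identical_samples_give_half_n_squared(self):
        U, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert U == pytest.approx(4.5)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_p_matches_exhaustive_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(40)[:5].astype(float)
        b = rng.permutation(40)[5:11].astype(float) + 0.5
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(_mwu_exact_p(a, b), abs=1e-9)

    def test_kw_consistent_with_mwu_for_two_groups(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1.2, 1, 10)
        _, p_kw = kruskal_wallis(a, b)
        _, p_mwu = mann_whitney(a, b)
        assert (p_kw < 0.05) == (p_mwu < 0.05)


class TestHolmBonferroni:
    def test_three_step_ladder(self):
        out = holm_bonferroni([0.5, 0.5, 0.5], alpha=0.05)
        assert sorted(out["threshold"]) == pytest.approx(
            [0.05 / 3, 0.025, 0.05])

    def test_all_p_one_rejects_nothing(self):
        assert not holm_bonferroni([1.0, 1.0, 1.0])["reject"].any()

    def test_step_down_rule_oracle(self):
        out = holm_bonferroni([0.001, 0.020, 0.040], alpha=0.05)
        assert out["reject"].all()

    def test_stop_at_first_failure(self):
        # 0.03 > 0.0167 stops the ladder; 0.001 alone is rejected
        out = holm_bonferroni([0.03, 0.001, 0.04], alpha=0.05)
        assert list(out["reject"]) == [False, True, False]

    def test_empty_input(self):
        assert holm_bonferroni([]).empty

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_rejections_are_a_prefix_of_the_sorted_order(self, ps):
        out = holm_bonferroni(ps)
        by_rank = out.sort_values("rank")["reject"].to_numpy()
        # once the ladder fails, everything after is retained
        if (~by_rank).any():
            first_fail = int(np.argmin(by_rank))
            assert not by_rank[first_fail:].any()

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_monotone_decisions(self, ps):
        out = holm_bonferroni(ps)
        for i in range(len(ps)):
            for j in range(len(ps)):
                if out.loc[j, "reject"] and ps[i] < ps[j]:
                    assert out.loc[i, "reject"]


class TestCorrelation:
    def test_perfect_linear_relation(self):
        r, p, cat = correlate_and_classify([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert cat == "very high"

    @pytest.mark.parametrize("r,expected", [
        (0.10, "little or no"), (-0.29, "little or no"),
        (0.30, "low"), (0.45, "low"),
        (0.55, "moderate"), (0.70, "moderate"),
        (0.75, "high"), (-0.85, "high"),
        (0.90, "very high"), (1.0, "very high"),
    ])
    def test_classification_bands(self, r, expected):
        assert classify_correlation(r) == expected

    def test_dichotomous_equal_group_means_give_zero(self):
        x = [0, 0, 0, 1, 1, 1]
        y = [1.0, 2.0, 3.0, 3.0, 2.0, 1.0]
        r, p, cat = correlate_and_classify(x, y, "dichotomous")
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_biserial_adjustment_inflates_point_biserial(self, rng):
        x = np.repeat([0, 1], 30)
        y = x * 1.0 + rng.normal(0, 1, 60)
        r_pb, _, _ = correlate_and_classify(x, y, "dichotomous")
        r_b, _, _ = correlate_and_classify(x, y, "biserial")
        assert abs(r_b) > abs(r_pb)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_and_classify([1, 1, 1], [1, 2, 3])

    def test_missing_pairs_dropped(self):
        r, _, _ = correlate_and_classify([1, 2, 3, np.nan], [2, 4, 6, 1])
        assert r == pytest.approx(1.0)


class TestStepwise:
    def _frame(self, rng, n=50, beta_grip=12.0, noise=2.2):
        grip = np.clip(rng.normal(0.55, 0.15, n), 0.05, 1.0)
        return pd.DataFrame({
            "APS": 4 + beta_grip * (1 - grip) + rng.normal(0, noise, n),
            "age": rng.uniform(5, 15, n),
            "macs": rng.integers(1, 4, n).astype(float),
            "grip_force": grip,
            "strength": rng.uniform(5, 20, n),
            "tone": rng.uniform(0, 15, n),
        })

    def test_grip_driven_cohort_selects_grip_first(self, rng):
        res = forward_stepwise_regression(self._frame(rng))
        assert res.selected[0] == "grip_force"
        assert res.step_r2 == sorted(res.step_r2)
        assert 0.0 <= res.final_r2 <= 1.0

    def test_grip_first_in_at_least_95_percent_of_200_replicates(self):
        cfg = SimulationConfig()
        hits = 0
        for i in range(200):
            df = simulate_clinical_cohort(cfg, seed=1000 + i,
                                          coupling="grip_only")
            res = forward_stepwise_regression(df[df["task"] == "HTH"])
            hits += bool(res.selected) and res.selected[0] == "grip_force"
        assert hits >= 190

    def test_pure_noise_mostly_yields_empty_model(self):
        cfg = SimulationConfig()
        empty = 0
        for i in range(100):
            df = simulate_clinical_cohort(cfg, seed=4000 + i, coupling="none")
            res = forward_stepwise_regression(df[df["task"] == "HTM"])
            empty += not res.selected
        # roughly (1 - alpha)^5 with correlated candidates; broad band
        assert empty >= 60

    def test_duplicated_predictor_tie_breaks_by_declared_order(self, rng):
        df = self._frame(rng)
        df["strength"] = df["grip_force"]  # exact duplicate, later in order
        res = forward_stepwise_regression(df)
        assert res.selected[0] == "grip_force"

    def test_r2_non_decreasing_and_final_matches_full_fit(self, rng):
        df = self._frame(rng, beta_grip=8.0, noise=1.0)
        df["APS"] += 0.3 * df["age"] + 0.5 * df["tone"]
        res = forward_stepwise_regression(df)
        assert res.step_r2 == sorted(res.step_r2)
        assert res.final_r2 == pytest.approx(res.step_r2[-1])

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError):
            forward_stepwise_regression(self._frame(rng, n=5))


class TestBattery:
    def test_macs_effect_flagged_only_where_injected(self, rng):
        # direct construction: wrist AVS carries a MACS gradient, trunk noise
        rows = []
        for i in range(45):
            macs = ["I", "II", "III"][i % 3]
            shift = {"I": 0.0, "II": 6.0, "III": 12.0}[macs]
            row = {"subject": f"S{i}", "task": "HTH",
                   "APS": rng.normal(8, 1)}
            for ch in ("wrist_flex_ext", "trunk_rot"):
                for fam in ("AVS", "PTA", "ROM"):
                    base = shift if ch == "wrist_flex_ext" else 0.0
                    row[f"{fam}_{ch}"] = rng.normal(base, 1.0)
            rows.append(row)
        outcomes = pd.DataFrame(rows)
        clinical = pd.DataFrame({
            "subject": [f"S{i}" for i in range(45)],
            "macs": [["I", "II", "III"][i % 3] for i in range(45)],
        })
        report = run_group_comparison(outcomes, clinical, run_regression=False)
        gt = report.group_tests.set_index("outcome")
        assert gt.loc["AVS_wrist_flex_ext", "reject"]
        assert not gt.loc["AVS_trunk_rot", "reject"]

    def test_posthoc_marked_not_applicable_for_single_subject_groups(self, rng):
        outcomes = pd.DataFrame([
            {"subject": f"S{i}", "task": "HTH",
             "APS": [1.0, 2.0, 10.0, 11.0, 30.0][i]}
            for i in range(5)
        ])
        clinical = pd.DataFrame({
            "subject": [f"S{i}" for i in range(5)],
            "macs": ["I", "I", "II", "II", "III"],
        })
        report = run_group_comparison(outcomes, clinical, run_regression=False)
        ph = report.posthoc
        if not ph.empty:
            iii = ph[ph["pair"].str.contains("III")]
            assert (~iii["applicable"]).all()

    def test_shuffled_labels_reject_at_most_alpha(self):
        cfg = SimulationConfig()
        rej = tot = 0
        for i in range(60):
            df = simulate_clinical_cohort(cfg, seed=7000 + i, coupling="none")
            d = df[df["task"] == "HTH"]
            groups = [d.loc[d["macs"] == g, "APS"] for g in ("I", "II", "III")]
            _, p = kruskal_wallis(*groups)
            rej += p < 0.05
            tot += 1
        assert rej / tot <= 0.05 + 2.5 * math.sqrt(0.05 * 0.95 / tot)
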