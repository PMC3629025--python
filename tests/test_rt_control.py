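"""RT-equating, RT-matching and RT-subsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rtbold as rb
from rtbold.rt_control import MatchedSet


def brute_force_max_matching(cong, incong, window):
    """Independent oracle: maximum bipartite matching via Hopcroft-Karp."""
    import networkx as nx

    g = nx.Graph()
    left = [f"L{i}" for i in range(len(cong))]
    right = [f"R{j}" for j in range(len(incong))]
    g.add_nodes_from(left, bipartite=0)
    g.add_nodes_from(right, bipartite=1)
    for i, c in enumerate(cong):
        for j, x in enumerate(incong):
            if abs(c - x) <= window:
                g.add_edge(f"L{i}", f"R{j}")
    m = nx.bipartite.maximum_matching(g, top_nodes=left)
    return len(m) // 2


class TestRTEquate:
    def test_zero_slope_collapses_to_uncorrected_effect(self):
        eq = rb.RTEquatedContrast(
            beta_cong_main=1.0, beta_incong_main=1.4, slope_cong=0.0,
            mean_rt_cong=686.9, mean_rt_incong=969.8,
        )
        assert eq.contrast == pytest.approx(eq.uncorrected)
        assert eq.congruent_eq == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        # slope 0.002 units/ms over a 282.9 ms RT difference adds 0.5658
        eq = rb.RTEquatedContrast(
            beta_cong_main=1.0, beta_incong_main=2.0, slope_cong=0.002,
            mean_rt_cong=686.9, mean_rt_incong=969.8,
        )
        assert eq.congruent_eq == pytest.approx(1.5658, abs=1e-12)
        assert eq.contrast == pytest.approx(2.0 - 1.5658, abs=1e-12)

    def test_missing_coefficients_raise(self, fitted):
        *_, fit = fitted
        with pytest.raises(KeyError):
            fit.coef("not_a_regressor")

    def test_rt_equate_from_fit_uses_named_coefficients(self, fitted):
        table, series, filt, design, fit = fitted
        eq = rb.rt_equate(fit, filt.mean_rt("congruent"),
                          filt.mean_rt("incongruent"))
        assert eq.beta_cong_main == fit.coef("congruent")
        assert eq.slope_cong == fit.coef("congruent_rt1")
        assert eq.uncorrected == pytest.approx(
            fit.coef("incongruent") - fit.coef("congruent")
        )

    def test_recovery_of_genuine_increment(self, small_spec, rt_model):
        """Cohorts generated with a real congruency increment: the group-mean
        equated contrast recovers the increment; with increment 0 it sits
        near 0."""
        for increment in (0.0, 0.4):
            contrasts = []
            for i in range(12):
                truth = rb.BoldTruth(rt_slope=0.002, noise_sd=0.5,
                                     congruency_increment=increment)
                table, series = rb.simulate_participant(
                    small_spec, rt_model, truth, seed=900 + i
                )
                filt = rb.filter_trials(table)
                design = rb.build_design(
                    table, filt, tr=small_spec.tr,
                    n_volumes_per_run=small_spec.n_volumes_per_run,
                )
                fit = rb.FirstLevelModel(series, design).fit()
                eq = rb.rt_equate(fit, filt.mean_rt("congruent"),
                                  filt.mean_rt("incongruent"))
                contrasts.append(eq.contrast)
            se = np.std(contrasts, ddof=1) / np.sqrt(len(contrasts))
            assert abs(np.mean(contrasts) - increment) < 3.5 * se + 0.02


class TestMatching:
    def test_worked_example_two_pairs(self):
        matched = rb.match_trials(
            [("a", 700.0), ("b", 710.0), ("c", 905.0)],
            [("x", 705.0), ("y", 712.0), ("z", 950.0)],
            window=10.0,
        )
        got = {(p.congruent_id, p.incongruent_id) for p in matched.pairs}
        assert got == {("a", "x"), ("b", "y")}
        # exhaustive enumeration confirms no matching of size 3 exists
        assert brute_force_max_matching([700, 710, 905], [705, 712, 950], 10) == 2

    def test_disjoint_rt_ranges_give_no_pairs(self):
        matched = rb.match_trials(
            [("a", 600.0), ("b", 620.0)], [("x", 900.0), ("y", 950.0)],
            window=10.0,
        )
        assert len(matched) == 0

    def test_identical_lists_match_perfectly(self):
        n = 7
        cong = [(f"c{i}", 700.0 + 5 * i) for i in range(n)]
        incong = [(f"i{i}", 700.0 + 5 * i) for i in range(n)]
        matched = rb.match_trials(cong, incong, window=10.0)
        assert len(matched) == n

    def test_empty_inputs_allowed(self):
        assert len(rb.match_trials([], [], window=10.0)) == 0

    def test_invalid_rt_rejected(self):
        with pytest.raises(ValueError):
            rb.match_trials([("a", -5.0)], [("x", 700.0)])

    def test_pair_bound_invariant_enforced(self):
        with pytest.raises(ValueError, match="window"):
            MatchedSet(
                pairs=[rb.rt_control.MatchedPair("a", "x", 700.0, 750.0)],
                window=10.0,
            )

    def test_disjoint_pairs_invariant_enforced(self):
        pair = rb.rt_control.MatchedPair("a", "x", 700.0, 705.0)
        with pytest.raises(ValueError, match="more than one"):
            MatchedSet(pairs=[pair, rb.rt_control.MatchedPair(
                "a", "y", 700.0, 702.0)], window=10.0)

    def test_deterministic_under_permutation(self):
        cong = [("a", 700.0), ("b", 710.0), ("c", 905.0)]
        incong = [("x", 705.0), ("y", 712.0), ("z", 950.0)]
        m1 = rb.match_trials(cong, incong)
        m2 = rb.match_trials(cong[::-1], incong[::-1])
        assert m1.pairs == m2.pairs

    @given(
        st.lists(st.integers(min_value=600, max_value=700), max_size=8),
        st.lists(st.integers(min_value=600, max_value=700), max_size=8),
        st.sampled_from([0, 5, 10, 25]),
    )
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_greedy_cardinality_is_optimal(self, cong_rts, incong_rts, window):
        cong = [(f"c{i}", float(rt)) for i, rt in enumerate(cong_rts)]
        incong = [(f"i{i}", float(rt)) for i, rt in enumerate(incong_rts)]
        matched = rb.match_trials(cong, incong, window=float(window))
        assert len(matched) == brute_force_max_matching(
            [r for _, r in cong], [r for _, r in incong], window
        )

    def test_matched_mean_rt_difference_bounded_by_window(self, participant):
        from tests.conftest import retained_rt_lists

        table, _, filt = participant
        cong, incong = retained_rt_lists(table, filt)
        matched = rb.match_trials(cong, incong, window=10.0)
        assert len(matched) > 0
        assert abs(matched.rt_effect()) <= 10.0


class TestSubsampling:
    def test_uniform_stride_example_110_100_50(self):
        cong = [(f"c{i}", 500.0 + i) for i in range(110)]
        incong = [(f"i{i}", 800.0 + i) for i in range(100)]
        sub = rb.subsample_trials(cong, incong, k=50)
        # strides 110/50 = 2.2 and 100/50 = 2.0
        cong_idx = [int(t[1:]) for t in sub.selected["congruent"]]
        incong_idx = [int(t[1:]) for t in sub.selected["incongruent"]]
        assert cong_idx == [int(np.floor(j * 110 / 50)) for j in range(50)]
        assert incong_idx == list(range(0, 100, 2))
        assert len(sub.selected["congruent"]) == 50
        assert len(sub.selected["incongruent"]) == 50

    def test_k_equal_n_selects_everything(self):
        cong = [(f"c{i}", 600.0 + i) for i in range(9)]
        incong = [(f"i{i}", 900.0 + i) for i in range(9)]
        sub = rb.subsample_trials(cong, incong, k=9)
        assert sorted(sub.selected["congruent"]) == sorted(t for t, _ in cong)

    def test_floor_rule_n10_k3(self):
        cong = [(f"c{i}", 600.0 + i) for i in range(10)]
        incong = [(f"i{i}", 900.0 + i) for i in range(10)]
        sub = rb.subsample_trials(cong, incong, k=3)
        assert [int(t[1:]) for t in sub.selected["congruent"]] == [0, 3, 6]

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError, match="cannot select"):
            rb.subsample_trials([("a", 700.0)], [("x", 900.0)], k=2)

    def test_selection_walks_sorted_rt_order(self):
        rng = np.random.default_rng(8)
        rts = rng.uniform(500, 1500, 20)
        cong = [(f"c{i}", rts[i]) for i in range(20)]
        sub = rb.subsample_trials(cong, cong, k=5)
        sel_rts = sorted(
            rts[int(t[1:])] for t in sub.selected["congruent"]
        )
        # selected RTs are spread through the distribution: one per quintile
        qs = np.quantile(rts, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        for v, lo, hi in zip(sel_rts, qs[:-1], qs[1:]):
            assert lo - 1e-9 <= v <= hi + 1e-9

    def test_subsampling_preserves_behavioral_effect(self, participant):
        from tests.conftest import retained_rt_lists

        table, _, filt = participant
        cong, incong = retained_rt_lists(table, filt)
        matched = rb.match_trials(cong, incong, window=10.0)
        sub = rb.subsample_trials(cong, incong, k=len(matched))
        rt = dict(zip(table["trial_id"], table["response_time"]))
        full_effect = (np.mean([r for _, r in incong])
                       - np.mean([r for _, r in cong]))
        sub_effect = (
            np.mean([rt[t] for t in sub.selected["incongruent"]])
            - np.mean([rt[t] for t in sub.selected["congruent"]])
        )
        assert abs(sub_effect - full_effect) < 30.0
        # count equality with the matched set, per condition
        for cond in ("congruent", "incongruent"):
            assert len(sub.selected[cond]) == len(matched)
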