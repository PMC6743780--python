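"""Group-comparison tests: mean matrices, modal labels, KS and intensity
comparisons, the Hochberg step-up correction and the universality rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ragamood import synth
from ragamood.ratings import (build_mean_matrix, compare_intensities,
                              filter_participants, hochberg_adjust,
                              ks_compare, modal_label, modal_label_agreement,
                              universality_verdict)


def make_table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "group",
                                       "familiarity", "raga", "mode",
                                       "emotion", "rating"])


def tiny_cell(ratings_e, ratings_ne, raga="r", mode="alaap", emotion="calm"):
    rows = []
    for i, r in enumerate(ratings_e):
        rows.append((f"E{i}", "E", 2.0, raga, mode, emotion, r))
    for i, r in enumerate(ratings_ne):
        rows.append((f"N{i}", "NE", 2.0, raga, mode, emotion, r))
    return make_table(rows)


# ---------------------------------------------------------------------------
# mean matrix
# ---------------------------------------------------------------------------

class TestMeanMatrix:
    def test_single_participant_matrix_equals_their_ratings(self):
        rows = [("P1", "E", 3.0, "r1", m, e, (i + j) % 5)
                for i, m in enumerate(("alaap", "gat"))
                for j, e in enumerate(synth.EMOTIONS)]
        mm = build_mean_matrix(make_table(rows), "E")
        for i, m in enumerate(("alaap", "gat")):
            for j, e in enumerate(synth.EMOTIONS):
                assert mm.means.loc[("r1", m), e] == (i + j) % 5

    def test_two_raters_average(self):
        t = tiny_cell([1], [2])
        t = pd.concat([t, tiny_cell([3], [2]).assign(participant_id="E9")])
        mm = build_mean_matrix(t, "E")
        assert mm.means.loc[("r", "alaap"), "calm"] == 2.0

    def test_full_design_shape_is_24_by_8(self, contrast_table):
        mm = build_mean_matrix(contrast_table, "E")
        assert mm.shape == (24, 8)
        assert mm.means.to_numpy().min() >= 0
        assert mm.means.to_numpy().max() <= 4

    def test_unknown_group_rejected(self, contrast_table):
        with pytest.raises(ValueError):
            build_mean_matrix(contrast_table, "XX")


class TestParticipantFilter:
    def test_participants_below_threshold_dropped(self, stimulus_triples):
        params = synth.RatingSimParams(n_participants={"E": 20, "NE": 20},
                                       p_complete=0.5, seed=3)
        t = synth.simulate_ratings(params, stimulus_triples)
        kept = filter_participants(t, 13)
        n_exc = kept.groupby("participant_id")[["raga", "mode"]].apply(
            lambda d: d.drop_duplicates().shape[0])
        assert (n_exc >= 13).all()
        assert kept["participant_id"].nunique() < t["participant_id"].nunique()


# ---------------------------------------------------------------------------
# modal labels
# ---------------------------------------------------------------------------

class TestModalLabel:
    def test_unanimous_top_emotion(self):
        rows = []
        for i in range(5):
            for e in synth.EMOTIONS:
                rows.append((f"P{i}", "E", 2.0, "r", "gat", e,
                             4 if e == "calm" else 1))
        assert modal_label(make_table(rows), "r", "gat", "E") == {"calm"}

    def test_two_way_tie_returns_both(self):
        rows = []
        for i, top in enumerate(["calm", "sad"] * 2):
            for e in synth.EMOTIONS:
                rows.append((f"P{i}", "E", 2.0, "r", "gat", e,
                             4 if e == top else 0))
        assert modal_label(make_table(rows), "r", "gat", "E") == {"calm", "sad"}

    def test_empty_cell_rejected(self, contrast_table):
        with pytest.raises(ValueError):
            modal_label(contrast_table, "nosuch", "gat", "E")

    def test_mean_rating_method(self):
        rows = []
        for i in range(3):
            for e in synth.EMOTIONS:
                rows.append((f"P{i}", "E", 2.0, "r", "gat", e,
                             3 if e == "sad" else 1))
        got = modal_label(make_table(rows), "r", "gat", "E",
                          method="mean_rating")
        assert got == {"sad"}

    def test_identical_processes_agree_on_most_excerpts(self, null_table):
        agr = modal_label_agreement(null_table)
        assert len(agr) == 24
        assert agr["agree"].sum() >= 20


# ---------------------------------------------------------------------------
# KS comparison
# ---------------------------------------------------------------------------

def brute_force_ks(a, b):
    """Max |ECDF difference| by direct evaluation at every sample point."""
    pts = np.unique(np.concatenate([a, b]))
    return max(abs(np.mean(a <= x) - np.mean(b <= x)) for x in pts)


class TestKS:
    def test_identical_samples_give_zero(self):
        t = tiny_cell([0, 1, 2, 3], [0, 1, 2, 3])
        D, p = ks_compare(t, "r", "alaap", "calm")
        assert D == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_samples_give_one(self):
        t = tiny_cell([0, 0, 0], [4, 4, 4])
        D, _ = ks_compare(t, "r", "alaap", "calm")
        assert D == 1.0

    def test_against_ecdf_oracle_example(self):
        t = tiny_cell([0, 1, 2], [2, 3, 4])
        D, _ = ks_compare(t, "r", "alaap", "calm")
        assert D == pytest.approx(brute_force_ks(np.array([0, 1, 2]),
                                                 np.array([2, 3, 4])))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.lists(st.integers(0, 4), min_size=2, max_size=6),
           b=st.lists(st.integers(0, 4), min_size=2, max_size=6))
    def test_statistic_matches_ecdf_oracle_on_discrete_samples(self, a, b):
        t = tiny_cell(a, b)
        D, _ = ks_compare(t, "r", "alaap", "calm")
        assert D == pytest.approx(brute_force_ks(np.array(a), np.array(b)))


# ---------------------------------------------------------------------------
# intensity comparisons
# ---------------------------------------------------------------------------

class TestCompareIntensities:
    def test_identical_group_samples_give_null_result(self):
        t = tiny_cell([1, 2, 3, 2], [1, 2, 3, 2])
        out = compare_intensities(t)
        welch = out[out["test"] == "welch"].iloc[0]
        assert welch["statistic"] == pytest.approx(0.0)
        assert welch["p"] == pytest.approx(1.0)

    def test_welch_statistic_from_group_summaries(self):
        """Welch t on familiarity-score summaries (141 vs 111 raters with
        means 2.86/1.99, SDs 1.09/1.02) evaluates to ~6.52."""
        m1, s1, n1 = 2.86, 1.09, 141
        m2, s2, n2 = 1.99, 1.02, 111
        t = (m1 - m2) / np.sqrt(s1 ** 2 / n1 + s2 ** 2 / n2)
        assert t == pytest.approx(6.521, abs=1e-3)
        # and scipy's Welch implementation agrees on matching raw data
        rng = np.random.default_rng(0)
        a = rng.normal(m1, s1, 4000)
        b = rng.normal(m2, s2, 4000)
        res = stats.ttest_ind(a, b, equal_var=False)
        manual = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / a.size
                                                 + b.var(ddof=1) / b.size)
        assert res.statistic == pytest.approx(manual)

    def test_family_size_is_192_per_test(self, contrast_table):
        out = compare_intensities(contrast_table)
        assert (out["test"] == "welch").sum() == 192
        assert (out["test"] == "wilcoxon").sum() == 192
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_missing_group_in_cell_rejected(self):
        t = tiny_cell([1, 2], [])
        with pytest.raises(ValueError):
            compare_intensities(t)


# ---------------------------------------------------------------------------
# Hochberg
# ---------------------------------------------------------------------------

def hochberg_oracle(p):
    """Direct min-over-step evaluation: adj(i) = min_{k>=i}(m-k+1)p(k)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min((m - k) * ps[k] for k in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestHochberg:
    def test_two_value_example(self):
        assert hochberg_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_tied_values_example(self):
        assert hochberg_adjust([0.03, 0.03, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert hochberg_adjust([0.2]) == pytest.approx([0.2])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            hochberg_adjust([])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1,
                      max_size=10))
    def test_matches_oracle_and_statsmodels(self, p):
        got = hochberg_adjust(p)
        assert got == pytest.approx(hochberg_oracle(p))
        sm = pytest.importorskip("statsmodels.stats.multitest")
        assert got == pytest.approx(
            sm.multipletests(p, method="simes-hochberg")[1])

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=40)
        adj = hochberg_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)


# ---------------------------------------------------------------------------
# universality rule
# ---------------------------------------------------------------------------

class TestUniversality:
    def test_reported_pattern_is_universal(self):
        # 18 significant among 192 comparisons
        adj = [0.01] * 18 + [0.5] * 174
        verdict, n_sig, frac = universality_verdict(adj)
        assert verdict
        assert n_sig == 18
        assert frac == pytest.approx(18 / 192)

    def test_threshold_is_strict_majority(self):
        above, below = [0.99], [0.001]
        assert universality_verdict(above * 97 + below * 95)[0]
        assert not universality_verdict(above * 96 + below * 96)[0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            universality_verdict([])


def test_null_simulation_type_one_control(stimulus_triples):
    """Under identical group processes both test families flag roughly
    alpha-level fractions raw and almost nothing after Hochberg."""
    params = synth.RatingSimParams(
        betas={"E": dict(synth.DEFAULT_BETAS_E),
               "NE": dict(synth.DEFAULT_BETAS_E)},
        familiarity={"E": (2.4, 1.05), "NE": (2.4, 1.05)},
        n_participants={"E": 50, "NE": 45}, p_complete=1.0, seed=55)
    table = synth.simulate_ratings(params, stimulus_triples)
    out = compare_intensities(table)
    for fam in ("welch", "wilcoxon"):
        sub = out[out["test"] == fam]
        assert (sub["p"] < 0.05).mean() < 0.15     # raw near alpha
        assert sub["significant"].sum() <= 2       # corrected near zero
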