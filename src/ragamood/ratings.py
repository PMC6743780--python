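"""Cross-group comparison of emotion labels and rating intensities.

Implements the survey-analysis stage: per-group 24 x 8 mean-rating
matrices, modal emotion labels per excerpt, Kolmogorov-Smirnov comparisons
of rating distributions, the family of 192 excerpt-by-emotion intensity
comparisons (Welch t and Wilcoxon rank-sum with continuity correction),
Hochberg step-up correction across the family, and the universality
verdict: universality is declared when strictly more than half of the
adjusted p-values exceed the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import EMOTIONS

ALPHA_DEFAULT = 0.05
MIN_EXCERPTS_RATED = 12  # inclusion threshold: rated at least half the set


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "group", "familiarity", "raga", "mode",
                "emotion", "rating"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    bad_mode = set(table["mode"].unique()) - {"alaap", "gat"}
    if bad_mode:
        raise ValueError(f"unknown modes: {sorted(bad_mode)}")
    bad_emo = set(table["emotion"].unique()) - set(EMOTIONS)
    if bad_emo:
        raise ValueError(f"unknown emotions: {sorted(bad_emo)}")
    r = table["rating"].to_numpy()
    if ((r < 0) | (r > 4)).any():
        raise ValueError("ratings must lie in [0, 4]")
    return table


def filter_participants(table: pd.DataFrame,
                        min_excerpts: int = MIN_EXCERPTS_RATED) -> pd.DataFrame:
    """Drop participants who rated fewer than ``min_excerpts`` excerpts."""
    n_exc = (table.groupby("participant_id")[["raga", "mode"]]
             .apply(lambda d: d.drop_duplicates().shape[0]))
    keep = n_exc[n_exc >= min_excerpts].index
    return table[table["participant_id"].isin(keep)]


@dataclass
class MeanRatingMatrix:
    """Per-group excerpt-by-emotion mean ratings with rater counts."""

    group: str
    means: pd.DataFrame    # (raga, mode) x emotion
    counts: pd.DataFrame

    @property
    def shape(self):
        return self.means.shape


def build_mean_matrix(table: pd.DataFrame, group: str) -> MeanRatingMatrix:
    """Average each excerpt/emotion cell over the group's raters."""
    t = _validate_table(table)
    t = t[t["group"] == group]
    if t.empty:
        raise ValueError(f"no ratings for group {group!r}")
    piv = t.pivot_table(index=["raga", "mode"], columns="emotion",
                        values="rating", aggfunc="mean")
    cnt = t.pivot_table(index=["raga", "mode"], columns="emotion",
                        values="rating", aggfunc="count")
    emotions = [e for e in EMOTIONS if e in piv.columns]
    piv = piv.reindex(columns=emotions)
    cnt = cnt.reindex(columns=emotions).fillna(0).astype(int)
    if piv.isna().any().any():
        empty = piv.stack(future_stack=True)
        empty = empty[empty.isna()].index.tolist()
        raise ValueError(f"cells with no ratings: {empty[:5]}...")
    return MeanRatingMatrix(group=group, means=piv, counts=cnt)


def modal_label(table: pd.DataFrame, raga: str, mode: str, group: str,
                method: str = "participant_argmax"):
    """Most frequently occurring emotion label for one excerpt and group.

    With ``participant_argmax`` (default), each participant contributes
    their maximum-rated emotion(s); within-participant ties share one vote
    equally.  With ``mean_rating``, the label(s) maximizing the cell mean
    are returned.  Ties at the excerpt level are returned as a frozenset.
    """
    t = _validate_table(table)
    t = t[(t["group"] == group) & (t["raga"] == raga) & (t["mode"] == mode)]
    if t.empty:
        raise ValueError(f"no ratings for excerpt ({raga}, {mode}) in group {group!r}")
    if method == "mean_rating":
        m = t.groupby("emotion")["rating"].mean()
        best = m[np.isclose(m, m.max())]
        return frozenset(best.index)
    if method != "participant_argmax":
        raise ValueError("method must be 'participant_argmax' or 'mean_rating'")
    votes = {}
    for _, d in t.groupby("participant_id"):
        mx = d["rating"].max()
        top = d.loc[d["rating"] == mx, "emotion"].tolist()
        for e in top:
            votes[e] = votes.get(e, 0.0) + 1.0 / len(top)
    s = pd.Series(votes)
    best = s[np.isclose(s, s.max())]
    return frozenset(best.index)


def modal_label_agreement(table: pd.DataFrame,
                          method: str = "participant_argmax") -> pd.DataFrame:
    """Per-excerpt modal labels for both groups and their agreement.

    Agreement means the two groups' (possibly tied) modal-label sets
    intersect.
    """
    rows = []
    for (raga, mode), _ in table.groupby(["raga", "mode"]):
        le = modal_label(table, raga, mode, "E", method)
        ln = modal_label(table, raga, mode, "NE", method)
        rows.append(dict(raga=raga, mode=mode,
                         label_E="|".join(sorted(le)),
                         label_NE="|".join(sorted(ln)),
                         agree=bool(le & ln)))
    return pd.DataFrame(rows)


def ks_compare(table: pd.DataFrame, raga: str, mode: str, emotion: str):
    """Two-sample KS test of the groups' rating distributions for one cell.

    Uses the asymptotic two-sided statistic; with 5-point discrete ratings
    ties are ubiquitous, so the p-value is approximate (the D statistic is
    exact).
    """
    t = _validate_table(table)
    cell = t[(t["raga"] == raga) & (t["mode"] == mode) & (t["emotion"] == emotion)]
    a = cell.loc[cell["group"] == "E", "rating"].to_numpy()
    b = cell.loc[cell["group"] == "NE", "rating"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 ratings per group")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_intensities(table: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                        tests=("welch", "wilcoxon")) -> pd.DataFrame:
    """Between-group intensity comparison for every excerpt x emotion cell.

    Runs a Welch t-test and/or a Wilcoxon rank-sum test (normal
    approximation with continuity correction) per cell, then applies the
    Hochberg step-up correction jointly across each test family.  On the
    full 12-raga, 2-mode, 8-emotion design each family has 192 members.
    """
    t = _validate_table(table)
    rows = []
    for (raga, mode, emo), cell in t.groupby(["raga", "mode", "emotion"]):
        a = cell.loc[cell["group"] == "E", "rating"].to_numpy(dtype=float)
        b = cell.loc[cell["group"] == "NE", "rating"].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"cell ({raga}, {mode}, {emo}) lacks ratings "
                             "from both groups")
        if "welch" in tests:
            if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                res = stats.ttest_ind(a, b, equal_var=False)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(dict(raga=raga, mode=mode, emotion=emo, test="welch",
                             statistic=stat, p=p))
        if "wilcoxon" in tests:
            try:
                res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic", use_continuity=True)
                stat, p = float(res.statistic), float(res.pvalue)
            except ValueError:  # all values identical
                stat, p = a.size * b.size / 2.0, 1.0
            rows.append(dict(raga=raga, mode=mode, emotion=emo, test="wilcoxon",
                             statistic=stat, p=p))
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for fam in out["test"].unique():
        mask = out["test"] == fam
        out.loc[mask, "p_adj"] = hochberg_adjust(out.loc[mask, "p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def hochberg_adjust(pvals) -> np.ndarray:
    """Hochberg step-up adjusted p-values, returned in input order.

    With order statistics p(1) <= ... <= p(m): adj(m) = p(m) and
    adj(i) = min(adj(i+1), (m - i + 1) * p(i)), capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    prev = p[order[-1]]
    adj_sorted[-1] = min(prev, 1.0)
    for i in range(m - 2, -1, -1):
        prev = min(prev, (m - i) * p[order[i]])
        adj_sorted[i] = min(prev, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def universality_verdict(adjusted_pvals, alpha: float = ALPHA_DEFAULT):
    """Universality rule on a family of adjusted p-values.

    Returns ``(verdict, n_significant, fraction_significant)``; the verdict
    is true iff strictly more than half of the adjusted p-values exceed
    ``alpha``.
    """
    p = np.asarray(adjusted_pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    n_sig = int((p <= alpha).sum())
    n_above = int((p > alpha).sum())
    return n_above > p.size / 2, n_sig, n_sig / p.size


def ks_label_comparison(table: pd.DataFrame,
                        alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """KS comparison of rating distributions for each excerpt's common
    modal emotion, across all excerpts where the groups' modal labels agree."""
    agreement = modal_label_agreement(table)
    rows = []
    for _, r in agreement[agreement["agree"]].iterrows():
        common = sorted(set(r["label_E"].split("|")) & set(r["label_NE"].split("|")))
        emo = common[0]
        D, p = ks_compare(table, r["raga"], r["mode"], emo)
        rows.append(dict(raga=r["raga"], mode=r["mode"], emotion=emo,
                         statistic=D, p=p, significant=p < alpha))
    return pd.DataFrame(rows)
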