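"""Recall-dynamics statistics: serial-position curves, temporal and
semantic clustering scores, and mixed-effects group contrasts.

The temporal clustering score follows the transition-percentile
convention: at each recall transition the serial-position distance of
the actually-recalled item is percentile-ranked against the distances
of every other item that had not yet been recalled, so 1.0 means every
transition went to the nearest available neighbour and 0.5 is the exact
chance level under uniformly random recall order.  Semantic clustering
uses the adjusted ratio of clustering (ARC), which normalizes the count
of adjacent same-category recalls between its chance expectation (0)
and its maximum (1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SchemaError, validate_events

__all__ = [
    "serial_position_curve",
    "list_temporal_percentiles",
    "temporal_clustering_score",
    "list_arc_score",
    "semantic_arc_score",
    "clustering_group_comparison",
    "recall_group_lr_test",
]


def serial_position_curve(events: pd.DataFrame) -> pd.DataFrame:
    """Per-subject recall probability at each serial position.

    Returns a subjects x positions DataFrame; the probability at
    position *p* is the fraction of presented items at *p* that were
    later recalled.
    """
    validate_events(events)
    curve = (
        events.assign(recalled=events["recalled"].astype(float))
        .pivot_table(index="subject", columns="serial_position",
                     values="recalled", aggfunc="mean")
    )
    return curve


def spc_group_summary(curve: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Group mean and standard error of the serial-position curve."""
    g = groups.reindex(curve.index)
    out = []
    for name, sub in curve.groupby(g):
        out.append(pd.DataFrame({
            "group": name,
            "serial_position": sub.columns,
            "mean": sub.mean(axis=0).to_numpy(),
            "sem": sub.sem(axis=0).to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def _recall_sequence(list_events: pd.DataFrame) -> pd.DataFrame:
    rec = list_events[list_events["recalled"].astype(bool)]
    return rec.sort_values("output_position")


def list_temporal_percentiles(list_events: pd.DataFrame) -> list[float]:
    """Transition percentile scores for a single list.

    For the transition from the item at output rank r to rank r+1, the
    candidate pool is every serial position not yet recalled (the item
    just recalled is excluded).  The recalled item's |lag| is scored as
    the fraction of the *other* candidates that are strictly farther
    plus half the fraction tied; transitions with no other candidate are
    skipped.
    """
    seq = _recall_sequence(list_events)["serial_position"].to_numpy()
    all_pos = list_events["serial_position"].to_numpy()
    scores: list[float] = []
    recalled_so_far: set[int] = set()
    for r in range(len(seq) - 1):
        recalled_so_far.add(int(seq[r]))
        candidates = np.array([p for p in all_pos if p not in recalled_so_far])
        target = seq[r + 1]
        others = candidates[candidates != target]
        if len(others) == 0:
            continue
        d_target = abs(int(target) - int(seq[r]))
        d_others = np.abs(others - seq[r])
        frac = (np.sum(d_others > d_target) + 0.5 * np.sum(d_others == d_target)) / len(others)
        scores.append(float(frac))
    return scores


def temporal_clustering_score(events: pd.DataFrame) -> pd.Series:
    """Mean transition percentile per subject (NaN if no transitions)."""
    validate_events(events)
    out = {}
    for subj, sub in events.groupby("subject"):
        scores: list[float] = []
        for _, lst in sub.groupby(["session", "list"]):
            scores.extend(list_temporal_percentiles(lst))
        out[subj] = float(np.mean(scores)) if scores else np.nan
    return pd.Series(out, name="temporal_score")


def list_arc_score(categories_in_recall_order: np.ndarray) -> float:
    """Adjusted ratio of clustering for one list's recall sequence.

    ``ARC = (R - E[R]) / (maxR - E[R])`` where R counts adjacent recall
    pairs from the same category, ``E[R] = sum_i n_i (n_i - 1) / N`` is
    the exact expectation of R under a uniformly random recall order
    (so chance maps to 0), and ``maxR = N - (number of categories
    recalled)``.  Returns NaN for degenerate lists (fewer than two
    recalls, or maxR equal to E[R], e.g. a single recalled category).
    """
    cats = np.asarray(categories_in_recall_order)
    n_total = len(cats)
    if n_total < 2:
        return np.nan
    r_obs = float(np.sum(cats[1:] == cats[:-1]))
    _, counts = np.unique(cats, return_counts=True)
    e_r = float(np.sum(counts * (counts - 1)) / n_total)
    max_r = float(n_total - len(counts))
    if max_r == e_r:
        return np.nan
    return (r_obs - e_r) / (max_r - e_r)


def semantic_arc_score(events: pd.DataFrame) -> pd.Series:
    """Per-subject mean ARC over categorized lists with a defined score."""
    validate_events(events)
    cat_events = events[events["task_variant"] == "categorized"]
    if len(cat_events) == 0:
        raise SchemaError("no categorized-task events for ARC scoring")
    out = {}
    for subj, sub in cat_events.groupby("subject"):
        scores = []
        for _, lst in sub.groupby(["session", "list"]):
            cats = _recall_sequence(lst)["category"].to_numpy()
            arc = list_arc_score(cats)
            if np.isfinite(arc):
                scores.append(arc)
        out[subj] = float(np.mean(scores)) if scores else np.nan
    return pd.Series(out, name="arc_score")


def clustering_group_comparison(scores: pd.Series, groups: pd.Series) -> dict:
    """Welch's t-test comparing per-subject clustering scores between groups."""
    g = groups.reindex(scores.index)
    levels = sorted(g.dropna().unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    a = scores[g == levels[0]].dropna()
    b = scores[g == levels[1]].dropna()
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "groups": levels,
            "n": (int(len(a)), int(len(b)))}


def recall_group_lr_test(events: pd.DataFrame, group_labels: pd.Series) -> dict:
    """Likelihood-ratio tests for group effects on per-item recall.

    Fits linear mixed models (maximum likelihood, random intercept per
    subject) to the 0/1 recalled outcome with group, task and serial
    position as fixed effects, and returns 1-df likelihood-ratio chi2
    statistics for (a) the group main effect and (b) the group x task
    interaction.  The interaction test requires both task variants.
    """
    import statsmodels.formula.api as smf

    validate_events(events)
    df = events.copy()
    df["recalled"] = df["recalled"].astype(float)
    df["group"] = group_labels.reindex(df["subject"]).to_numpy()
    if df["group"].isna().any():
        raise ValueError("every subject needs a group label")
    if df["group"].nunique() < 2:
        raise ValueError("need two groups for a group contrast")
    counts = df.groupby("group")["subject"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 subjects per group")

    def _fit(formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject"])
            try:
                res = model.fit(reml=False)
            except np.linalg.LinAlgError:
                return None  # degenerate fit; flagged below
        return res

    def _lr(full, reduced):
        if full is None or reduced is None:
            return np.nan, np.nan, False
        if not (np.isfinite(full.llf) and np.isfinite(reduced.llf)):
            return np.nan, np.nan, False
        chi2 = 2.0 * (full.llf - reduced.llf)
        return float(chi2), float(stats.chi2.sf(chi2, df=1)), True

    base = "recalled ~ C(serial_position)"
    full_main = _fit(base + " + task_variant + group")
    red_main = _fit(base + " + task_variant")
    chi2_group, p_group, ok = _lr(full_main, red_main)
    out = {
        "chi2_group": chi2_group,
        "p_group": p_group,
        "converged": bool(ok and all(
            getattr(m, "converged", False) for m in (full_main, red_main))),
    }
    if df["task_variant"].nunique() == 2:
        full_int = _fit(base + " + group * task_variant")
        red_int = _fit(base + " + group + task_variant")
        chi2_int, p_int, ok = _lr(full_int, red_int)
        out["chi2_interaction"] = chi2_int
        out["p_interaction"] = p_int
        out["converged"] = out["converged"] and bool(ok and all(
            getattr(m, "converged", False) for m in (full_int, red_int)))
    else:
        out["chi2_interaction"] = np.nan
        out["p_interaction"] = np.nan
    return out
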