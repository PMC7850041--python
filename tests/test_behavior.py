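"""Recall-dynamics statistics against hand computations and oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_events
from memsme import behavior as bhv
from memsme.datatypes import SchemaError
from memsme.simulate import EffectTruth, SimConfig, generate_behavioral_session


def brute_force_temporal(positions_all, recall_seq):
    """Independent transition-percentile oracle (plain loops over the
    enumerated candidate set at every transition)."""
    scores = []
    recalled = []
    for r in range(len(recall_seq) - 1):
        recalled.append(recall_seq[r])
        cands = [p for p in positions_all if p not in recalled]
        target = recall_seq[r + 1]
        others = [p for p in cands if p != target]
        if not others:
            continue
        dt = abs(target - recall_seq[r])
        greater = sum(abs(p - recall_seq[r]) > dt for p in others)
        ties = sum(abs(p - recall_seq[r]) == dt for p in others)
        scores.append((greater + 0.5 * ties) / len(others))
    return scores


class TestTemporalClustering:
    def test_hand_enumerated_four_item_list(self):
        # studied 1-2-3-4, recalled in order 1, 4, 2: both transitions
        # go to the farthest available item -> score 0
        ev = make_events([{"list": 1, "n": 4, "recalled_order": [1, 4, 2]}])
        scores = bhv.list_temporal_percentiles(ev)
        assert scores == [0.0, 0.0]
        assert bhv.temporal_clustering_score(ev)["S0"] == 0.0

    def test_perfect_study_order_scores_one(self):
        ev = make_events([{"list": 1, "recalled_order": list(range(1, 13))}])
        assert bhv.temporal_clustering_score(ev)["S0"] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_lists(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        k = int(rng.integers(2, n + 1))
        order = (rng.permutation(n)[:k] + 1).tolist()
        ev = make_events([{"list": 1, "n": n, "recalled_order": order}])
        got = bhv.list_temporal_percentiles(ev)
        want = brute_force_temporal(list(range(1, n + 1)), order)
        assert got == pytest.approx(want, abs=1e-10)

    def test_no_transitions_gives_nan(self):
        ev = make_events([{"list": 1, "recalled_order": [5]}])
        assert np.isnan(bhv.temporal_clustering_score(ev)["S0"])

    def test_depends_only_on_recall_positions(self):
        # renaming items must not change the score
        ev = make_events([{"list": 1, "recalled_order": [3, 4, 9]}])
        ev2 = ev.copy()
        ev2["item"] = ["X" + str(i) for i in range(len(ev2))]
        a = bhv.temporal_clustering_score(ev)["S0"]
        b = bhv.temporal_clustering_score(ev2)["S0"]
        assert a == b


class TestScoreBoundsProperty:
    """Score-range invariants over arbitrary recall sequences."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_temporal_in_unit_interval_and_arc_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        k = int(rng.integers(2, n + 1))
        order = (rng.permutation(n)[:k] + 1).tolist()
        cats = rng.integers(0, 3, n).tolist()
        ev = make_events([{"list": 1, "n": n, "recalled_order": order,
                           "categories": cats,
                           "task_variant": "categorized"}])
        t = bhv.temporal_clustering_score(ev)["S0"]
        assert np.isnan(t) or 0.0 <= t <= 1.0
        a = bhv.semantic_arc_score(ev)["S0"]
        assert np.isnan(a) or a <= 1.0


class TestArc:
    def test_hand_computed_blocked_six_recalls(self):
        # categories in recall order A A B B C C: R=3, E(R)=1.2, maxR=3
        assert bhv.list_arc_score(np.array([0, 0, 1, 1, 2, 2])) == pytest.approx(1.0)

    def test_perfectly_blocked_twelve_item_list(self):
        cats = [0] * 4 + [1] * 4 + [2] * 4
        ev = make_events([
            {"list": 1, "task_variant": "categorized", "categories": cats,
             "recalled_order": list(range(1, 13))}
        ])
        assert bhv.semantic_arc_score(ev)["S0"] == pytest.approx(1.0)

    def test_category_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        cats = rng.integers(0, 3, 10)
        relabeled = np.array([2, 0, 1])[cats]
        assert bhv.list_arc_score(cats) == pytest.approx(bhv.list_arc_score(relabeled))

    def test_degenerate_lists_return_nan(self):
        assert np.isnan(bhv.list_arc_score(np.array([0])))
        assert np.isnan(bhv.list_arc_score(np.array([0, 0, 0])))  # maxR == E(R)

    def test_alternating_categories_score_negative(self):
        # A B A B A B: no same-category adjacency, below chance
        assert bhv.list_arc_score(np.array([0, 1, 0, 1, 0, 1])) < 0

    def test_requires_categorized_events(self):
        ev = make_events([{"list": 1, "recalled_order": [1, 2]}])
        with pytest.raises(SchemaError):
            bhv.semantic_arc_score(ev)


class TestSerialPositionCurve:
    def test_all_recalled_gives_ones(self):
        ev = make_events([{"list": 1, "recalled_order": list(range(1, 13))}])
        assert (bhv.serial_position_curve(ev).loc["S0"] == 1.0).all()

    def test_none_recalled_gives_zeros(self):
        ev = make_events([{"list": 1, "recalled_order": []}])
        assert (bhv.serial_position_curve(ev).loc["S0"] == 0.0).all()

    def test_direct_count(self):
        ev = make_events([
            {"list": 1, "recalled_order": [1]},
            {"list": 2, "recalled_order": []},
        ])
        curve = bhv.serial_position_curve(ev).loc["S0"]
        assert curve[1] == 0.5
        assert curve[2] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(SchemaError):
            bhv.serial_position_curve(pd.DataFrame())


class TestGroupTests:
    def _two_group_events(self, shift, n_per_group=6, seed0=50):
        frames, labels = [], {}
        rng = np.random.default_rng(seed0)
        base = 0.25 + 0.35 * np.exp(-np.arange(12) / 2.5)
        for g, delta in enumerate((0.0, shift)):
            for i in range(n_per_group):
                subj_shift = rng.normal(0, 0.06)  # between-subject ability
                truth = EffectTruth(
                    recall_base=np.clip(base + delta + subj_shift, 0.02, 0.98))
                subj = f"G{g}S{i}"
                frames.append(generate_behavioral_session(
                    SimConfig(n_lists=12), truth, seed0 + 100 * g + i, subject=subj))
                labels[subj] = "case" if g else "control"
        return pd.concat(frames, ignore_index=True), pd.Series(labels)

    def test_group_effect_detected(self):
        ev, labels = self._two_group_events(shift=-0.18)
        res = bhv.recall_group_lr_test(ev, labels)
        assert res["p_group"] < 0.05
        assert res["converged"]

    def test_single_group_rejected(self):
        ev, labels = self._two_group_events(shift=0.0, n_per_group=3)
        with pytest.raises(ValueError):
            bhv.recall_group_lr_test(ev, labels.map(lambda _: "case"))

    def test_interaction_detected_when_injected_in_one_task(self):
        frames, labels = [], {}
        rng = np.random.default_rng(77)
        base = 0.25 + 0.35 * np.exp(-np.arange(12) / 2.5)
        for g in range(2):
            for i in range(5):
                subj = f"G{g}S{i}"
                subj_shift = rng.normal(0, 0.06)
                for variant in ("unrelated", "categorized"):
                    # group 1 is impaired only on the categorized task
                    delta = -0.22 if (g == 1 and variant == "categorized") else 0.0
                    truth = EffectTruth(recall_base=np.clip(
                        base + delta + subj_shift, 0.02, 0.98))
                    cfg = SimConfig(n_lists=10, task_variant=variant)
                    sess = 0 if variant == "unrelated" else 1
                    frames.append(generate_behavioral_session(
                        cfg, truth, 700 + 100 * g + 10 * sess + i,
                        subject=subj, session=sess))
                labels[subj] = "case" if g else "control"
        ev = pd.concat(frames, ignore_index=True)
        res = bhv.recall_group_lr_test(ev, pd.Series(labels))
        assert res["p_interaction"] < 0.05

    def test_welch_comparison_of_clustering_scores(self):
        scores = pd.Series({"a": 0.6, "b": 0.62, "c": 0.58, "d": 0.5, "e": 0.52, "f": 0.48})
        groups = pd.Series({"a": "x", "b": "x", "c": "x", "d": "y", "e": "y", "f": "y"})
        res = bhv.clustering_group_comparison(scores, groups)
        assert res["t"] > 0 and 0 < res["p"] < 0.05
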