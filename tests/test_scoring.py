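"""Path scoring against brute-force oracles and the path statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from galevo.experiments import FeatureKind, FeatureTable
from galevo.networks import (EvolutionaryEvent, EvolutionaryPath,
                             POST_WGD_ANCESTOR, applicable_events,
                             apply_event, enumerate_configurations,
                             enumerate_paths)
from galevo.scoring import (event_fold_change, path_statistics, score_path,
                            score_all_paths)

EV = EvolutionaryEvent


def synthetic_table(seed: int) -> FeatureTable:
    """Feature table with random positive values (no simulation)."""
    rng = np.random.default_rng(seed)
    values = {}
    for cfg in enumerate_configurations():
        values[cfg.vector] = {
            f: float(10.0 ** rng.uniform(2, 5)) for f in FeatureKind}
    return FeatureTable(values=values, n_replicates=1, seed=seed)


def brute_force_score(path, feature, table):
    """Oracle: recompute every step penalty directly from the definitions."""
    total = 0.0
    cfg = POST_WGD_ANCESTOR
    for ev in path.event_order:
        folds = {}
        for alt in applicable_events(cfg):
            child = apply_event(cfg, alt)
            folds[alt] = (table.values[child.vector][feature]
                          / table.values[cfg.vector][feature])
        if feature.maximized:
            total += np.log10(folds[ev] / max(folds.values()))
        else:
            total += np.log10(min(folds.values()) / folds[ev])
        cfg = apply_event(cfg, ev)
    return total


class TestStepScores:
    def test_fold_change_of_neutral_edge(self):
        table = synthetic_table(0)
        table.values[apply_event(POST_WGD_ANCESTOR,
                                 EV.LOSE_GAL2_DUP).vector] = dict(
            table.values[POST_WGD_ANCESTOR.vector])
        fold = event_fold_change(POST_WGD_ANCESTOR, EV.LOSE_GAL2_DUP,
                                 FeatureKind.REPRESSION_STRENGTH, table)
        assert fold == pytest.approx(1.0)

    def test_fold_changes_reciprocal_under_role_swap(self):
        table = synthetic_table(1)
        child = apply_event(POST_WGD_ANCESTOR, EV.SPECIALIZE_GAL1)
        fwd = event_fold_change(POST_WGD_ANCESTOR, EV.SPECIALIZE_GAL1,
                                FeatureKind.INDUCTION_STRENGTH, table)
        rev = (table.values[POST_WGD_ANCESTOR.vector]
               [FeatureKind.INDUCTION_STRENGTH]
               / table.values[child.vector][FeatureKind.INDUCTION_STRENGTH])
        assert fwd * rev == pytest.approx(1.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_on_random_tables(self, seed):
        table = synthetic_table(seed)
        paths = enumerate_paths()[:10]
        for path in paths:
            for feature in FeatureKind:
                got = score_path(path, feature, table).total
                want = brute_force_score(path, feature, table)
                assert got == pytest.approx(want, abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_penalties_non_positive_and_last_step_null(self, seed):
        table = synthetic_table(seed)
        for path in enumerate_paths()[::13]:
            for feature in FeatureKind:
                ps = score_path(path, feature, table)
                assert all(s.penalty <= 0.0 for s in ps.steps)
                assert ps.steps[-1].penalty == 0.0  # single available event
                assert ps.total <= 0.0

    def test_greedy_path_scores_zero(self):
        table = synthetic_table(42)
        for feature in FeatureKind:
            cfg = POST_WGD_ANCESTOR
            order = []
            for _ in range(5):
                folds = {ev: event_fold_change(cfg, ev, feature, table)
                         for ev in applicable_events(cfg)}
                pick = (max if feature.maximized else min)(folds, key=folds.get)
                order.append(pick)
                cfg = apply_event(cfg, pick)
            path = EvolutionaryPath.from_events(order)
            assert score_path(path, feature, table).total == 0.0

    def test_antisymmetry_of_optimization_sense(self):
        # inverting all feature values swaps max- and min-sense scores
        table = synthetic_table(3)
        inverted = FeatureTable(
            values={vec: {FeatureKind.SWITCH_EFFECTIVENESS:
                          1.0 / feats[FeatureKind.INDUCTION_STRENGTH]}
                    for vec, feats in table.values.items()},
            n_replicates=1, seed=3)
        for path in enumerate_paths()[::17]:
            a = score_path(path, FeatureKind.INDUCTION_STRENGTH, table).total
            b = score_path(path, FeatureKind.SWITCH_EFFECTIVENESS,
                           inverted).total
            # INDUCTION is maximized, SWITCH_EFFECTIVENESS minimized: same
            # penalties on reciprocal folds
            assert a == pytest.approx(b, abs=1e-12)


class TestToyHypercube:
    """Exhaustive oracle on a reduced 3-event space."""

    EVENTS = (EV.SPECIALIZE_GAL1, EV.LOSE_GAL2_DUP, EV.LOSE_GAL80_DUP)

    def test_scores_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        # feature values over the 8 reachable corners of the sub-cube
        values = {}
        for mask in itertools.product((0, 1), repeat=3):
            cfg = POST_WGD_ANCESTOR
            for on, ev in zip(mask, self.EVENTS):
                if on:
                    cfg = apply_event(cfg, ev)
            values.setdefault(cfg.vector, {})[
                FeatureKind.REPRESSION_STRENGTH] = float(
                    10.0 ** rng.uniform(2, 5))

        def toy_score(order):
            total, cfg = 0.0, POST_WGD_ANCESTOR
            for ev in order:
                avail = [e for e in self.EVENTS
                         if e in applicable_events(cfg)]
                folds = {a: values[apply_event(cfg, a).vector]
                         [FeatureKind.REPRESSION_STRENGTH]
                         / values[cfg.vector][FeatureKind.REPRESSION_STRENGTH]
                         for a in avail}
                total += np.log10(min(folds.values()) / folds[ev])
                cfg = apply_event(cfg, ev)
            return total

        scores = [toy_score(p) for p in
                  itertools.permutations(self.EVENTS)]
        assert len(scores) == 6
        assert max(scores) == pytest.approx(0.0, abs=1e-12)
        assert all(s <= 1e-12 for s in scores)


class TestPathStatistics:
    def test_group_sizes(self):
        table = synthetic_table(5)
        by = {f: score_all_paths(f, table) for f in FeatureKind}
        st_ = path_statistics(by)
        assert st_["n_paths"] == 120
        assert st_["gal80_last_repression"]["group_n"] == 24
        assert st_["gal80_last_repression"]["rest_n"] == 96
        assert st_["spec_first_effectiveness"]["group_n"] == 12
        assert st_["spec_first_effectiveness"]["rest_n"] == 108

    def test_max_score_is_zero_for_each_feature(self):
        table = synthetic_table(6)
        for f in FeatureKind:
            totals = [ps.total for ps in score_all_paths(f, table)]
            assert max(totals) == pytest.approx(0.0, abs=1e-12)

    def test_welch_and_pooled_agree_on_equal_variances(self):
        table = synthetic_table(8)
        by = {f: score_all_paths(f, table) for f in FeatureKind}
        w = path_statistics(by, welch=True)
        p = path_statistics(by, welch=False)
        # same group means either way; t statistics close for n=24 vs 96
        assert w["gal80_last_repression"]["group_mean"] == \
            p["gal80_last_repression"]["group_mean"]

    def test_mismatched_score_lists_rejected(self):
        table = synthetic_table(9)
        by = {f: score_all_paths(f, table) for f in FeatureKind}
        by[FeatureKind.INDUCTION_STRENGTH] = \
            by[FeatureKind.INDUCTION_STRENGTH][:50]
        with pytest.raises(ValueError):
            path_statistics(by)
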