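"""Scoring of evolutionary paths and the associated path statistics.

Each of the five post-duplication steps of a path is penalized by the
log10 ratio of the observed event's feature fold-change to the best
fold-change among the events available at that intermediate:

    s = sum_i log10(x_obs_i / max_a x_a_i)     (maximized features)
    s = sum_i log10(min_a x_a_i / x_obs_i)     (minimized features)

Penalties are never positive; a path scores 0 exactly when it makes a
greedy (best-available) choice at every step, and the final step always
contributes 0 because only one event remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .experiments import FeatureKind, FeatureTable
from .networks import (EvolutionaryEvent, EvolutionaryPath,
                       NetworkConfiguration, applicable_events, apply_event,
                       enumerate_paths)

__all__ = [
    "StepScore",
    "PathScore",
    "event_fold_change",
    "score_path",
    "score_all_paths",
    "path_statistics",
    "scores_to_frame",
]


@dataclass(frozen=True)
class StepScore:
    """Penalty of one step against its best available alternative."""

    step: int                      # 1..5
    event: EvolutionaryEvent
    observed_fold: float
    alternative_folds: dict[EvolutionaryEvent, float]
    penalty: float


@dataclass(frozen=True)
class PathScore:
    path: EvolutionaryPath
    feature: FeatureKind
    steps: tuple[StepScore, ...]
    total: float


def event_fold_change(parent: NetworkConfiguration,
                      event: EvolutionaryEvent,
                      feature: FeatureKind,
                      table: FeatureTable) -> float:
    """feature(child) / feature(parent) for one evolutionary edge."""
    child = apply_event(parent, event)
    return table.value(child, feature) / table.value(parent, feature)


def score_path(path: EvolutionaryPath, feature: FeatureKind,
               table: FeatureTable) -> PathScore:
    """Sum of the five log10 step penalties of ``path`` for ``feature``.

    Scoring begins after the genome duplication: the walk from the post-WGD
    ancestor (``path.networks[1]``) to *S. cerevisiae*.  Ties with the best
    alternative incur zero penalty.
    """
    steps = []
    total = 0.0
    for i, event in enumerate(path.event_order, start=1):
        parent = path.networks[i]
        folds = {ev: event_fold_change(parent, ev, feature, table)
                 for ev in applicable_events(parent)}
        observed = folds[event]
        if feature.maximized:
            penalty = np.log10(observed / max(folds.values()))
        else:
            penalty = np.log10(min(folds.values()) / observed)
        penalty = min(penalty, 0.0)  # guard against fp noise on ties
        steps.append(StepScore(i, event, observed, folds, penalty))
        total += penalty
    return PathScore(path, feature, tuple(steps), total)


def score_all_paths(feature: FeatureKind, table: FeatureTable,
                    paths: list[EvolutionaryPath] | None = None
                    ) -> list[PathScore]:
    """Scores of all 120 paths (max over paths is exactly 0)."""
    paths = paths if paths is not None else enumerate_paths()
    return [score_path(p, feature, table) for p in paths]


def scores_to_frame(scores_by_feature: dict[FeatureKind, list[PathScore]]
                    ) -> pd.DataFrame:
    rows = []
    for feature, scores in scores_by_feature.items():
        for ps in scores:
            rows.append({
                "events": ">".join(e.name for e in ps.path.event_order),
                "feature": feature.label,
                **{f"penalty_{s.step}": s.penalty for s in ps.steps},
                "total": ps.total,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# path statistics


def _separation(path: EvolutionaryPath, inclusive: bool = False) -> int:
    """Events separating the two specialization events.

    Default counts the events strictly between them (0..3); the
    ``inclusive`` convention (positional distance, 1..4) is kept as an
    alternative because the published axis is not defined numerically.
    """
    order = [e for e in path.event_order]
    d = abs(order.index(EvolutionaryEvent.SPECIALIZE_GAL1)
            - order.index(EvolutionaryEvent.SPECIALIZE_GAL3))
    return d if inclusive else d - 1


def _events_before(path: EvolutionaryPath, event: EvolutionaryEvent) -> int:
    return [e for e in path.event_order].index(event)


def path_statistics(scores_by_feature: dict[FeatureKind, list[PathScore]],
                    welch: bool = True,
                    inclusive_separation: bool = False) -> dict:
    """Regressions and group contrasts over the 120 path scores.

    Returns a nested dict with (i) R^2 of repression and effectiveness
    scores against the number of events separating the two specializations,
    (ii) R^2 of induction scores against the number of events preceding
    GAL1 specialization, (iii) the GAL80-loss-last vs rest contrast on
    repression scores, (iv) the specializations-first vs rest contrast on
    effectiveness scores, and (v) cross-feature score correlations.
    Two-sample tests use Welch's unequal-variance form unless
    ``welch=False``.
    """
    rep = scores_by_feature[FeatureKind.REPRESSION_STRENGTH]
    ind = scores_by_feature[FeatureKind.INDUCTION_STRENGTH]
    eff = scores_by_feature[FeatureKind.SWITCH_EFFECTIVENESS]
    if not (len(rep) == len(ind) == len(eff)):
        raise ValueError("feature score lists must cover the same paths")
    paths = [ps.path for ps in rep]

    sep = np.array([_separation(p, inclusive_separation) for p in paths])
    early1 = np.array([_events_before(p, EvolutionaryEvent.SPECIALIZE_GAL1)
                       for p in paths])
    late3 = np.array([_events_before(p, EvolutionaryEvent.SPECIALIZE_GAL3)
                      for p in paths])
    s_rep = np.array([ps.total for ps in rep])
    s_ind = np.array([ps.total for ps in ind])
    s_eff = np.array([ps.total for ps in eff])

    def regression(x, y):
        res = stats.linregress(x, y)
        return {"slope": res.slope, "intercept": res.intercept,
                "r_squared": res.rvalue ** 2, "p_value": res.pvalue}

    def contrast(mask, y):
        a, b = y[mask], y[~mask]
        if a.size < 2 or b.size < 2:
            raise ValueError("each contrast group needs at least two paths")
        t = stats.ttest_ind(a, b, equal_var=not welch)
        return {"group_mean": a.mean(), "group_sd": a.std(ddof=1),
                "rest_mean": b.mean(), "rest_sd": b.std(ddof=1),
                "group_n": int(a.size), "rest_n": int(b.size),
                "t_statistic": t.statistic, "p_value": t.pvalue}

    g80_last = np.array(
        [p.event_order[-1] is EvolutionaryEvent.LOSE_GAL80_DUP
         for p in paths])
    spec_first = np.array(
        [{p.event_order[0], p.event_order[1]} ==
         {EvolutionaryEvent.SPECIALIZE_GAL1,
          EvolutionaryEvent.SPECIALIZE_GAL3} for p in paths])

    corr = {}
    for (na, ya), (nb, yb) in [(("repression", s_rep), ("induction", s_ind)),
                               (("repression", s_rep),
                                ("effectiveness", s_eff)),
                               (("induction", s_ind),
                                ("effectiveness", s_eff))]:
        r = stats.pearsonr(ya, yb)
        corr[f"{na}_vs_{nb}"] = {"r": r.statistic,
                                 "r_squared": r.statistic ** 2,
                                 "p_value": r.pvalue}

    return {
        "n_paths": len(paths),
        "separation_vs_repression": regression(sep, s_rep),
        "separation_vs_effectiveness": regression(sep, s_eff),
        "gal1_earliness_vs_induction": regression(early1, s_ind),
        "gal3_earliness_vs_induction": regression(late3, s_ind),
        "gal80_last_repression": contrast(g80_last, s_rep),
        "spec_first_effectiveness": contrast(spec_first, s_eff),
        "cross_feature": corr,
        "best_paths": {
            feature.label: [
                [e.name for e in ps.path.event_order]
                for ps in scores_by_feature[feature]
                if ps.total >= -1e-12]
            for feature in FeatureKind},
    }
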