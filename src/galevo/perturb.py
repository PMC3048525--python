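"""Robustness of the path-score analysis to random parameter perturbations.

Each replicate of the experiment rescores all 120 evolutionary paths after
drawing a random, non-persistent parameter change at every network
intermediate (*S. cerevisiae* itself is never perturbed).  Perturbations
model transient minor mutations: they apply to a single network and are
discarded, so feature values cannot be cached across intermediates the way
the unperturbed pipeline caches them.  Draw ranges follow the published
perturbation classes:

* kinetic parameters (mass-action rates, transport coefficients):
  multiplicative 10^U(-1,1);
* degradation rate and burst factor: multiplicative 2^U(-1,1);
* per-site transcription contributions (and constitutive rates):
  multiplicative 2^U(-1,1);
* binding and cooperative free energies: additive U(-1,1) kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .experiments import (FeatureKind, FeatureTable, network_features)
from .networks import (S_CEREVISIAE, PRE_WGD_ANCESTOR,
                       enumerate_configurations, enumerate_paths)
from .scoring import path_statistics, score_all_paths
from .simulate import SimulationParams

__all__ = ["PerturbationSpec", "PerturbationResult", "perturb_parameters",
           "perturbed_path_scores"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Perturbation draw ranges (exponents/shifts) and replication.

    Setting every range to zero collapses the spec to the identity.
    """

    kinetic_log10_range: float = 1.0
    degradation_burst_log2_range: float = 1.0
    contribution_log2_range: float = 1.0
    binding_energy_shift: float = 1.0
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kinetic_log10_range, self.degradation_burst_log2_range,
               self.contribution_log2_range, self.binding_energy_shift) < 0:
            raise ValueError("perturbation ranges must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def perturb_parameters(params: SimulationParams, spec: PerturbationSpec,
                       rng: np.random.Generator) -> SimulationParams:
    """One fresh, independently drawn parameter set; ``params`` untouched.

    Every parameter within a class receives its own draw (a shared factor
    on a forward/reverse rate pair would cancel in the equilibrium ratios
    and perturb nothing).
    """
    def mul10(x):
        return x * 10.0 ** rng.uniform(-spec.kinetic_log10_range,
                                       spec.kinetic_log10_range)

    def mul2(x, r):
        return x * 2.0 ** rng.uniform(-r, r)

    rates = params.rates
    new_rates = replace(rates, **{
        name: (mul10(kf), mul10(kr))
        for name in ("k3", "k13", "k380", "k1380", "k480")
        for kf, kr in [getattr(rates, name)]})
    transport = replace(params.transport,
                        a=mul10(params.transport.a),
                        b_transport=mul10(params.transport.b_transport))

    r_db = spec.degradation_burst_log2_range
    gamma = mul2(params.gamma, r_db)
    burst = mul2(params.burst, r_db)

    r_c = spec.contribution_log2_range
    archs = {}
    for gene, arch in params.resolved_architectures().items():
        archs[gene] = replace(
            arch,
            contributions=tuple(mul2(c, r_c) for c in arch.contributions),
            constitutive=mul2(arch.constitutive, r_c))

    shift = spec.binding_energy_shift
    th = params.thermo
    thermo = replace(
        th,
        dG_bind=th.dG_bind + rng.uniform(-shift, shift),
        dG_coop_44=th.dG_coop_44 + rng.uniform(-shift, shift),
        dG_coop_8080=th.dG_coop_8080 + rng.uniform(-shift, shift))

    return replace(params, rates=new_rates, transport=transport,
                   gamma=gamma, burst=burst, architectures=archs,
                   thermo=thermo)


@dataclass(frozen=True)
class PerturbationResult:
    """Per-replicate path scores plus recomputed statistics.

    ``scores`` is a long-format frame (replicate, events, feature, total);
    ``statistics`` holds one :func:`galevo.scoring.path_statistics` dict per
    replicate; ``degenerate_replicates`` lists replicates in which some
    perturbation abolished switch-like behavior (a feature value collapsed
    to zero), which are recorded but not fatal.
    """

    scores: pd.DataFrame
    statistics: list[dict]
    degenerate_replicates: list[int]

    def totals(self, feature: FeatureKind) -> np.ndarray:
        sel = self.scores[self.scores["feature"] == feature.label]
        return sel["total"].to_numpy()


_FLOOR = 1e-9


def _perturbed_feature_table(base: SimulationParams, spec: PerturbationSpec,
                             replicate: int, n_feature_replicates: int
                             ) -> tuple[FeatureTable, bool]:
    values = {}
    degenerate = False
    configs = sorted(enumerate_configurations(), key=lambda c: c.vector)
    for cfg in configs:
        if cfg == PRE_WGD_ANCESTOR:
            continue  # paths are scored only after the duplication
        stream = np.random.default_rng(
            np.random.SeedSequence((spec.seed, replicate, *cfg.vector)))
        if cfg == S_CEREVISIAE:
            p = base  # the extant network keeps the reference parameters
        else:
            p = perturb_parameters(base, spec, stream)
        sim_seed = int(stream.integers(2 ** 31))
        feats = network_features(cfg, replace(p, seed=sim_seed),
                                 n_feature_replicates)
        if min(feats.values()) <= 0.0:
            degenerate = True
            feats = {k: max(v, _FLOOR) for k, v in feats.items()}
        values[cfg.vector] = feats
    table = FeatureTable(values=values, n_replicates=n_feature_replicates,
                         seed=spec.seed)
    return table, degenerate


def perturbed_path_scores(base_params: SimulationParams,
                          spec: PerturbationSpec,
                          n_feature_replicates: int = 10
                          ) -> PerturbationResult:
    """Score all 120 paths under per-intermediate parameter perturbations.

    For each of ``spec.n_replicates`` replicates, every network except
    *S. cerevisiae* is simulated with its own independently perturbed
    parameter set, the per-replicate feature table is rebuilt, all paths
    are rescored for the three features and the path statistics are
    recomputed.  ``base_params`` is never modified (non-persistence).
    """
    paths = enumerate_paths()
    rows = []
    stats_out = []
    degenerate = []
    for r in range(spec.n_replicates):
        table, bad = _perturbed_feature_table(base_params, spec, r,
                                              n_feature_replicates)
        if bad:
            degenerate.append(r)
        by_feature = {f: score_all_paths(f, table, paths)
                      for f in FeatureKind}
        stats_out.append(path_statistics(by_feature))
        for f, scores in by_feature.items():
            for ps in scores:
                rows.append({
                    "replicate": r,
                    "events": ">".join(e.name for e in ps.path.event_order),
                    "feature": f.label,
                    "total": ps.total})
    return PerturbationResult(scores=pd.DataFrame(rows),
                              statistics=stats_out,
                              degenerate_replicates=degenerate)
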