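"""Hybrid simulator: propensities, Gillespie stepping and endpoint behavior."""

from dataclasses import replace

import numpy as np
import pytest

from galevo.networks import GeneId, S_CEREVISIAE
from galevo.signaling import SPECIES, ProteinPool
from galevo.simulate import (N_CHANNELS, N_SPECIES, SimulationParams,
                             SimulationState, degradation_propensities,
                             equilibrium_distribution, gillespie_step,
                             run_simulation, synthesis_propensities)

GAL4_ONLY = {GeneId.GAL4: 1}


class TestPropensities:
    def test_channel_inventory_is_17_and_18_species(self):
        syn = synthesis_propensities(S_CEREVISIAE, ProteinPool(),
                                     SimulationParams())
        deg = degradation_propensities(ProteinPool())
        assert len(syn) + len(deg) == N_CHANNELS == 17
        # 11 proteins + 6 genes + intracellular galactose
        assert len(deg) + len(syn) + 1 == N_SPECIES == 18

    def test_gal4_constitutive_synthesis_scales_with_copies(self):
        params = SimulationParams(synthesis_scale=1.0)
        one = synthesis_propensities({GeneId.GAL4: 1}, ProteinPool(), params)
        two = synthesis_propensities({GeneId.GAL4: 2}, ProteinPool(), params)
        assert one[GeneId.GAL4] == pytest.approx(0.06)
        assert two[GeneId.GAL4] == pytest.approx(0.12)
        assert one[GeneId.GAL1] == 0.0  # absent genes: zero-propensity channel

    def test_degradation_is_count_times_gamma(self):
        deg = degradation_propensities(ProteinPool(gal1p=500.0), gamma=0.002)
        assert deg["gal1p"] == pytest.approx(1.0)
        assert sum(degradation_propensities(ProteinPool()).values()) == 0.0


class TestGillespieStep:
    def test_mean_waiting_time_of_single_channel(self):
        params = SimulationParams(synthesis_scale=1.0)
        taus = []
        for i in range(300):
            state = SimulationState(0.0, ProteinPool(), GAL4_ONLY,
                                    np.random.default_rng(i))
            taus.append(gillespie_step(state, params).time)
        want = 1.0 / 0.06
        se = want / np.sqrt(len(taus))
        assert abs(np.mean(taus) - want) < 3 * se

    def test_burst_is_integer_with_mean_burst_factor(self):
        params = SimulationParams(synthesis_scale=1.0)
        bursts = []
        for i in range(400):
            state = SimulationState(0.0, ProteinPool(), GAL4_ONLY,
                                    np.random.default_rng(i))
            bursts.append(gillespie_step(state, params).pool.gal4p)
        assert set(bursts) <= {2.0, 3.0}
        assert np.mean(bursts) == pytest.approx(2.5, abs=0.1)

    def test_complex_degrades_whole(self):
        pool = ProteinPool(gal4_80p=50.0)
        state = SimulationState(0.0, pool, {}, np.random.default_rng(0))
        out = gillespie_step(state, SimulationParams())
        assert out.pool.gal4_80p == 49.0
        assert out.pool.gal4p == 0.0 and out.pool.gal80p == 0.0

    def test_quiescence_signalled(self):
        state = SimulationState(0.0, ProteinPool(), {},
                                np.random.default_rng(0))
        with pytest.raises(RuntimeError, match="quiescent"):
            gillespie_step(state, SimulationParams())


class TestRunSimulation:
    def test_zero_horizon_returns_initial_pool(self):
        pool = ProteinPool(gal1p=7.0, gal4p=3.0)
        res = run_simulation(S_CEREVISIAE,
                             SimulationParams(t_end=0.0, gal_out=1e-8),
                             initial_pool=pool)
        assert res.n_events == 0
        assert res.endpoint.gal1p == 7.0

    def test_identical_seed_reproduces_trajectory(self):
        params = SimulationParams(gal_out=1e-8, t_end=800.0, seed=99,
                                  record_every=100.0)
        a = run_simulation(S_CEREVISIAE, params)
        b = run_simulation(S_CEREVISIAE, params)
        assert a.n_events == b.n_events
        assert np.array_equal(a.endpoint.as_array(), b.endpoint.as_array())
        assert a.trajectory.equals(b.trajectory)

    def test_quiescent_configuration_terminates(self):
        res = run_simulation({}, SimulationParams(t_end=5000.0))
        assert res.n_events == 0
        assert np.all(res.endpoint.as_array() == 0.0)

    def test_birth_death_limit_matches_analytic_mean(self):
        # constitutive GAL4 with signaling disabled is a bursty birth-death
        # process with mean copies*f*scale*b/gamma
        n_rep = 60
        params = SimulationParams(gal_out=0.0, t_end=4000.0, seed=7)
        summ = equilibrium_distribution(GAL4_ONLY, params, n_rep)
        want = 0.06 * params.synthesis_scale * params.burst / params.gamma
        se = summ.sd["gal4p"] / np.sqrt(n_rep)
        assert abs(summ.mean["gal4p"] - want) < 3 * se

    def test_endpoint_counts_non_negative(self, fast_params):
        for gal in (1e-8, 1e-4):
            res = run_simulation(S_CEREVISIAE,
                                 replace(fast_params, gal_out=gal, seed=3))
            assert np.all(res.endpoint.as_array() >= 0.0)

    def test_switch_behavior_of_extant_network(self, fast_params):
        lo = equilibrium_distribution(
            S_CEREVISIAE, replace(fast_params, gal_out=1e-8), 4)
        hi = equilibrium_distribution(
            S_CEREVISIAE, replace(fast_params, gal_out=0.1), 4)
        assert hi.mean["gal1p"] > 10 * lo.mean["gal1p"]

    def test_endpoint_mean_invariant_to_det_skip_scale(self, default_params):
        # approximation validity: equilibration every n-th iteration with n
        # spanning a 10x range leaves equilibrium behavior unchanged
        base = replace(default_params, gal_out=1e-8, t_end=3000.0, seed=17)
        means, ses = [], []
        n_rep = 8
        for skip in (300.0, 3000.0):
            summ = equilibrium_distribution(
                S_CEREVISIAE, replace(base, det_skip_scale=skip), n_rep)
            g3 = sum(summ.mean[k] for k in ("gal3p_i", "gal3p_a", "gal3_80p"))
            means.append(g3)
            ses.append(summ.sd["gal3p_i"] / np.sqrt(n_rep))
        tol = 4 * np.hypot(*ses) + 0.05 * means[0]
        assert abs(means[0] - means[1]) < tol


class TestEquilibriumDistribution:
    def test_single_replicate_has_zero_sd(self, fast_params):
        summ = equilibrium_distribution(
            S_CEREVISIAE, replace(fast_params, gal_out=1e-8, t_end=500.0), 1)
        assert (summ.sd == 0.0).all()

    def test_replicate_count_validated(self, fast_params):
        with pytest.raises(ValueError):
            equilibrium_distribution(S_CEREVISIAE, fast_params, 0)

    def test_gal4_mean_is_galactose_independent(self, fast_params):
        lo = equilibrium_distribution(
            S_CEREVISIAE, replace(fast_params, gal_out=1e-8), 4)
        hi = equilibrium_distribution(
            S_CEREVISIAE, replace(fast_params, gal_out=0.1), 4)
        t4_lo = lo.mean["gal4p"] + lo.mean["gal4_80p"]
        t4_hi = hi.mean["gal4p"] + hi.mean["gal4_80p"]
        assert t4_hi == pytest.approx(t4_lo, rel=0.15)
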