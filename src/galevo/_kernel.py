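"""Numba-compiled core loop of the hybrid simulator.

The state vector ``x`` holds real-valued molecule counts of the 11 protein
species (order as in :data:`galevo.signaling.SPECIES`).  Synthesis and
degradation are sampled with the Gillespie algorithm; every ``n``-th
iteration the fast signaling reactions are re-partitioned to equilibrium at
fixed family totals, with ``n`` scaled linearly with the number of
molecules participating in the deterministic step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: synthesis product slot per gene (GAL1,GAL2,GAL3,GAL4,GAL80,GAL1/3);
#: GAL3 and GAL1/3 produce the inactive protein forms.
SYN_TARGET = np.array([0, 1, 2, 5, 7, 8], dtype=np.int64)


@njit(cache=True)
def _partition(x, galin, a3k, a13k, b380, b1380, b480):
    """Equilibrate the fast reactions in place at fixed family totals."""
    t3 = x[2] + x[3] + x[4]
    t13 = x[8] + x[9] + x[10]
    t4 = x[5] + x[6]
    t80 = x[7] + x[4] + x[10] + x[6]
    a3 = a3k * galin
    a13 = a13k * galin

    r = 0.0
    if t80 > 0.0:
        lo = 0.0
        hi = t80
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            s = 1.0
            if t3 > 0.0:
                s += t3 * a3 * b380 / (1.0 + a3 * (1.0 + b380 * mid))
            if t13 > 0.0:
                s += t13 * a13 * b1380 / (1.0 + a13 * (1.0 + b1380 * mid))
            if t4 > 0.0:
                s += b480 * t4 / (1.0 + b480 * mid)
            if mid * s < t80:
                lo = mid
            else:
                hi = mid
        r = 0.5 * (lo + hi)

    if t4 > 0.0:
        x[5] = t4 / (1.0 + b480 * r)
        x[6] = t4 - x[5]
    else:
        x[5] = 0.0
        x[6] = 0.0
    if t3 > 0.0:
        x[2] = t3 / (1.0 + a3 * (1.0 + b380 * r))
        x[3] = a3 * x[2]
        x[4] = b380 * x[3] * r
    else:
        x[2] = 0.0
        x[3] = 0.0
        x[4] = 0.0
    if t13 > 0.0:
        x[8] = t13 / (1.0 + a13 * (1.0 + b1380 * r))
        x[9] = a13 * x[8]
        x[10] = b1380 * x[9] * r
    else:
        x[8] = 0.0
        x[9] = 0.0
        x[10] = 0.0
    x[7] = max(t80 - x[4] - x[10] - x[6], 0.0)


@njit(cache=True)
def _synthesis_propensities(x, copies, scale, offsets, n4, n480, Kst, pref,
                            constit, wpm, out):
    """Per-gene synthesis propensities from the packed promoter tables."""
    w4 = wpm * x[5]
    w480 = wpm * x[6]
    for g in range(6):
        if copies[g] == 0:
            out[g] = 0.0
            continue
        lo = offsets[g]
        hi = offsets[g + 1]
        if hi == lo:
            f = constit[g]
        else:
            num = 0.0
            den = 0.0
            for s in range(lo, hi):
                w = pref[s]
                for _ in range(n4[s]):
                    w *= w4
                for _ in range(n480[s]):
                    w *= w480
                num += Kst[s] * w
                den += w
            f = num / den
            if f < 0.0:
                f = 0.0
        out[g] = copies[g] * f * scale


@njit(cache=True)
def run_kernel(x, copies, galout, t_end, seed,
               gamma, burst_mean, burst_fixed, scale, det_skip,
               a_t, b_t, a3k, a13k, b380, b1380, b480,
               offsets, n4, n480, Kst, pref, constit, wpm,
               rec_times, rec_out):
    """Hybrid Gillespie/equilibrium loop; modifies ``x`` in place.

    Returns the number of stochastic reaction events executed.
    ``rec_times`` is an increasing grid of sample times (may be empty);
    ``rec_out`` receives the state at the first iteration reaching each.
    """
    np.random.seed(seed)
    t = 0.0
    n_events = 0
    rec_i = 0
    n_rec = rec_times.shape[0]
    syn = np.zeros(6)
    since_det = 0
    n_det = 1
    burst_lo = int(np.floor(burst_mean))
    burst_frac = burst_mean - burst_lo

    while t < t_end:
        if since_det == 0:
            galin = galout * (a_t + b_t * x[1])
            _partition(x, galin, a3k, a13k, b380, b1380, b480)
            det_mol = (x[2] + x[3] + x[4] + x[5] + x[6] + x[7]
                       + x[8] + x[9] + x[10])
            n_det = int(det_mol / det_skip)
            if n_det < 1:
                n_det = 1
            _synthesis_propensities(x, copies, scale, offsets, n4, n480,
                                    Kst, pref, constit, wpm, syn)

        while rec_i < n_rec and rec_times[rec_i] <= t:
            for k in range(11):
                rec_out[rec_i, k] = x[k]
            rec_i += 1

        a_syn = 0.0
        for g in range(6):
            a_syn += syn[g]
        a_deg = 0.0
        for k in range(11):
            a_deg += x[k]
        a_deg *= gamma
        a0 = a_syn + a_deg
        if a0 <= 0.0:
            break  # quiescent: no channel can ever fire again

        t += np.random.exponential(1.0 / a0)
        if t >= t_end:
            t = t_end
            break

        u = np.random.random() * a0
        tf_changed = False
        if u < a_syn:
            g = 0
            acc = syn[0]
            while u >= acc and g < 5:
                g += 1
                acc += syn[g]
            if burst_fixed:
                burst = burst_mean
            else:
                burst = float(burst_lo)
                if np.random.random() < burst_frac:
                    burst += 1.0
            tgt = SYN_TARGET[g]
            x[tgt] += burst
            if tgt == 5:
                tf_changed = True
        else:
            u -= a_syn
            k = 0
            acc = gamma * x[0]
            while u >= acc and k < 10:
                k += 1
                acc += gamma * x[k]
            x[k] -= 1.0
            if x[k] < 0.0:
                x[k] = 0.0
            if k == 5 or k == 6:
                tf_changed = True
        n_events += 1

        if tf_changed:
            _synthesis_propensities(x, copies, scale, offsets, n4, n480,
                                    Kst, pref, constit, wpm, syn)

        since_det += 1
        if since_det >= n_det:
            since_det = 0

    while rec_i < n_rec:
        for k in range(11):
            rec_out[rec_i, k] = x[k]
        rec_i += 1
    return n_events
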