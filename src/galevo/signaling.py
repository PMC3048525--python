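"""Galactose transport and the fast signal-transduction equilibrium.

The deterministic half of each hybrid step.  Intracellular galactose is an
algebraic boundary condition set by the transport relation
``gal_in = gal_out * (a + b * Gal2p)`` (Gal2p as a molecule count), and the
five reversible mass-action reactions

    gal_in + Gal3p_i   <-> Gal3p_a          (k3+,   k3-)
    gal_in + Gal1/3p_i <-> Gal1/3p_a        (k13+,  k13-)
    Gal3p_a   + Gal80p <-> Gal3-80p         (k380+, k380-)
    Gal1/3p_a + Gal80p <-> Gal1/3-80p       (k1380+,k1380-)
    Gal80p    + Gal4p  <-> Gal4-80p         (k480+, k480-)

are solved to their joint equilibrium without advancing simulation time.
Galactose activation uses molar units (gal_in appears catalytically and is
clamped, not consumed); protein-protein mass action interprets the rate
constants per nanomolar at the 23 fL cellular volume (see the methods
note on units).  Given the four conserved family totals the equilibrium is
unique, and is found exactly by a monotone one-dimensional solve for free
Gal80p rather than by integrating the stiff ODE system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import counts_to_nanomolar

__all__ = [
    "TransportParams",
    "KineticRates",
    "ProteinPool",
    "SPECIES",
    "intracellular_galactose",
    "equilibrate",
    "EquilibrationError",
]

#: The 11 protein species, in canonical state-vector order.
SPECIES: tuple[str, ...] = (
    "gal1p", "gal2p", "gal3p_i", "gal3p_a", "gal3_80p",
    "gal4p", "gal4_80p", "gal80p", "gal13p_i", "gal13p_a", "gal13_80p",
)


@dataclass(frozen=True)
class TransportParams:
    """Galactose import coefficients (dimensionless).

    ``a`` models non-specific hexose transporters, ``b_transport`` the
    contribution per Gal2p permease molecule.
    """

    a: float = 0.001
    b_transport: float = 0.01

    def __post_init__(self) -> None:
        if self.a < 0 or self.b_transport < 0:
            raise ValueError("transport coefficients must be non-negative")


def intracellular_galactose(gal_out: float, gal2p_count: float,
                            params: TransportParams | None = None) -> float:
    """Clamped intracellular galactose concentration (molar).

    Recomputed at every deterministic step; extracellular galactose is an
    unconsumed boundary condition.
    """
    if gal_out < 0 or gal2p_count < 0:
        raise ValueError("gal_out and gal2p_count must be non-negative")
    params = params or TransportParams()
    return gal_out * (params.a + params.b_transport * gal2p_count)


@dataclass(frozen=True)
class KineticRates:
    """Forward/reverse rate constant pairs of the five fast reactions.

    Only the equilibrium ratios k+/k- matter to the hybrid scheme (the fast
    reactions are treated as instantaneous).  Galactose-activation ratios
    are per molar; protein-protein ratios are per nanomolar at the cellular
    volume.
    """

    k3: tuple[float, float] = (10.0, 1.0)
    k13: tuple[float, float] = (10.0, 1.0)
    k380: tuple[float, float] = (10.0, 1.0)
    k1380: tuple[float, float] = (10.0, 1.0)
    k480: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("k3", "k13", "k380", "k1380", "k480"):
            kf, kr = getattr(self, name)
            if kf < 0 or kr <= 0:
                raise ValueError(f"{name}: forward rate must be >= 0 and "
                                 "reverse rate > 0")

    @property
    def K3(self) -> float:
        return self.k3[0] / self.k3[1]

    @property
    def K13(self) -> float:
        return self.k13[0] / self.k13[1]

    @property
    def K380(self) -> float:
        return self.k380[0] / self.k380[1]

    @property
    def K1380(self) -> float:
        return self.k1380[0] / self.k1380[1]

    @property
    def K480(self) -> float:
        return self.k480[0] / self.k480[1]


@dataclass(frozen=True)
class ProteinPool:
    """Molecule counts of the 11 protein species plus intracellular galactose.

    Counts are integers after stochastic updates but real-valued between
    deterministic solves; ``gal_in`` is a molar concentration.
    """

    gal1p: float = 0.0
    gal2p: float = 0.0
    gal3p_i: float = 0.0
    gal3p_a: float = 0.0
    gal3_80p: float = 0.0
    gal4p: float = 0.0
    gal4_80p: float = 0.0
    gal80p: float = 0.0
    gal13p_i: float = 0.0
    gal13p_a: float = 0.0
    gal13_80p: float = 0.0
    gal_in: float = 0.0

    def __post_init__(self) -> None:
        if any(getattr(self, s) < 0 for s in SPECIES) or self.gal_in < 0:
            raise ValueError("molecule counts and gal_in must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray, gal_in: float = 0.0) -> "ProteinPool":
        return cls(**dict(zip(SPECIES, map(float, x))), gal_in=gal_in)

    # conserved family totals ------------------------------------------------
    @property
    def total_gal3_family(self) -> float:
        return self.gal3p_i + self.gal3p_a + self.gal3_80p

    @property
    def total_gal13_family(self) -> float:
        return self.gal13p_i + self.gal13p_a + self.gal13_80p

    @property
    def total_gal80_family(self) -> float:
        return self.gal80p + self.gal3_80p + self.gal13_80p + self.gal4_80p

    @property
    def total_gal4_family(self) -> float:
        return self.gal4p + self.gal4_80p


class EquilibrationError(RuntimeError):
    """Equilibrium solve failed to reach the residual tolerance."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        super().__init__(f"signaling equilibrium residual {residual:.3e} "
                         f"exceeds tolerance {tol:.3e}")


def _free_gal80(t3: float, t13: float, t4: float, t80: float,
                a3: float, a13: float, b380: float, b1380: float,
                b480: float, n_iter: int = 200) -> float:
    """Solve the scalar equilibrium condition for free Gal80p.

    ``a3``/``a13`` are the (dimensionless) galactose-activation odds
    K*gal_in; ``b*`` are per-molecule association constants.  The mapping
    r -> bound-Gal80 total is strictly increasing, so bisection on
    [0, t80] is globally convergent.
    """
    if t80 <= 0.0:
        return 0.0

    def excess(r: float) -> float:
        s3 = t3 * a3 * b380 / (1.0 + a3 * (1.0 + b380 * r)) if t3 > 0 else 0.0
        s13 = (t13 * a13 * b1380 / (1.0 + a13 * (1.0 + b1380 * r))
               if t13 > 0 else 0.0)
        s4 = b480 * t4 / (1.0 + b480 * r) if t4 > 0 else 0.0
        return r * (1.0 + s3 + s13 + s4) - t80

    lo, hi = 0.0, t80
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if excess(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def equilibrate(pool: ProteinPool, rates: KineticRates | None = None,
                gal_in: float | None = None, *,
                rtol: float = 1e-9) -> ProteinPool:
    """Equilibrium of the fast reactions at fixed conserved totals.

    Returns a new pool at the joint steady state of the five reversible
    reactions, holding ``gal_in`` constant (defaults to ``pool.gal_in``).
    Family totals are preserved exactly; the returned pool satisfies
    detailed balance for every reaction.  Simulation time is a concept of
    the caller and is not advanced here.
    """
    rates = rates or KineticRates()
    g = pool.gal_in if gal_in is None else gal_in
    if g < 0:
        raise ValueError("gal_in must be non-negative")

    t3 = pool.total_gal3_family
    t13 = pool.total_gal13_family
    t80 = pool.total_gal80_family
    t4 = pool.total_gal4_family

    sigma = counts_to_nanomolar(1.0)  # nM per molecule at the cell volume
    a3 = rates.K3 * g
    a13 = rates.K13 * g
    b380 = rates.K380 * sigma
    b1380 = rates.K1380 * sigma
    b480 = rates.K480 * sigma

    r = _free_gal80(t3, t13, t4, t80, a3, a13, b380, b1380, b480)

    gal4p = t4 / (1.0 + b480 * r) if t4 > 0 else 0.0
    gal4_80p = t4 - gal4p
    if t3 > 0:
        gal3p_i = t3 / (1.0 + a3 * (1.0 + b380 * r))
        gal3p_a = a3 * gal3p_i
        gal3_80p = b380 * gal3p_a * r
    else:
        gal3p_i = gal3p_a = gal3_80p = 0.0
    if t13 > 0:
        gal13p_i = t13 / (1.0 + a13 * (1.0 + b1380 * r))
        gal13p_a = a13 * gal13p_i
        gal13_80p = b1380 * gal13p_a * r
    else:
        gal13p_i = gal13p_a = gal13_80p = 0.0

    gal80p = t80 - gal3_80p - gal13_80p - gal4_80p
    # bisection leaves a bounded residual on the Gal80 balance; fold it into
    # the free-species slot and verify it is negligible
    residual = abs(gal80p - r)
    scale = max(t80, 1.0)
    if residual > 1e-6 * scale:
        raise EquilibrationError(residual / scale, 1e-6)

    return ProteinPool(
        gal1p=pool.gal1p, gal2p=pool.gal2p,
        gal3p_i=gal3p_i, gal3p_a=gal3p_a, gal3_80p=gal3_80p,
        gal4p=gal4p, gal4_80p=gal4_80p, gal80p=max(gal80p, 0.0),
        gal13p_i=gal13p_i, gal13p_a=gal13p_a, gal13_80p=gal13_80p,
        gal_in=g,
    )
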