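"""Statistical-mechanical promoter occupancy model.

Each upstream activating sequence (UAS) of a GAL promoter is empty, bound
by the activator Gal4p, or bound by the repressive Gal4-80p complex.  A
promoter's transcription propensity is the Boltzmann-weighted average, over
all ``3^n`` occupancy configurations, of the summed per-site contributions
to transcript initiation:

    f = max(0, sum_c K_c w_c / sum_c w_c),
    w_c = ([Gal4]/c0)^n4 * ([Gal4-80]/c0)^n480 * exp(-dG_c / beta),

where ``dG_c`` collects one binding free energy per occupied site plus one
cooperative term per adjacently bound like pair (Gal4p-Gal4p or
Gal4-80p-Gal4-80p; mixed adjacent pairs contribute nothing), with the
all-empty configuration as the zero-energy reference.  Contributions K_c
can be negative (active repression), so the final average is clamped at
zero.  A promoter without UASs is constitutive.

The reference concentration ``c0`` fixes the statistical-weight units; its
default, together with the effective repressor-pair cooperative energy, was
calibrated once against the published *S. cerevisiae* equilibrium molecule
counts (see the methods note).  The equivalent per-site dissociation
constant c0*exp(dG_bind/beta) is about 2.7 uM.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np

from .networks import GeneId
from .units import AVOGADRO, NUCLEAR_VOLUME_L

__all__ = [
    "ThermoConstants",
    "PromoterArchitecture",
    "SiteState",
    "OccupancyState",
    "enumerate_occupancies",
    "promoter_propensity",
    "default_architectures",
]


@dataclass(frozen=True)
class ThermoConstants:
    """Energy scales of the occupancy model (kcal/mol) and the weight units.

    ``beta`` is the published energy constant (1.68 kcal/mol); statistical
    weights are exp(-dG/beta) so that favorable (negative) free energies
    stabilize occupancy.  ``dG_coop_8080`` is an effective value: the
    cooperative energies are calibration parameters of the model (they were
    fitted, not measured), and under this sign convention the repressor-pair
    energy that reproduces the published GAL1 switch is -5.6 kcal/mol.
    ``tf_ref_conc`` (molar) is the reference concentration entering the
    statistical weights.
    """

    beta: float = 1.68
    dG_bind: float = -13.86
    dG_coop_44: float = -2.00
    dG_coop_8080: float = -5.60
    tf_ref_conc: float = 1.02e-2

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.tf_ref_conc <= 0:
            raise ValueError("tf_ref_conc must be positive")

    @property
    def site_weight_per_molecule(self) -> float:
        """Per-site statistical weight of one bound TF molecule.

        Combines the nuclear-volume count->molar conversion, the reference
        concentration and the binding Boltzmann factor.
        """
        conc_per_molecule = 1.0 / (AVOGADRO * NUCLEAR_VOLUME_L)
        return (conc_per_molecule / self.tf_ref_conc
                * math.exp(-self.dG_bind / self.beta))


class SiteState(enum.IntEnum):
    EMPTY = 0
    GAL4 = 1
    GAL480 = 2


@dataclass(frozen=True)
class PromoterArchitecture:
    """UAS count, cooperative pairing and per-site contributions of a promoter.

    ``contributions`` is the (empty, Gal4p-bound, Gal4-80p-bound) triple of
    per-site contributions to transcript production; ``constitutive`` is the
    fixed propensity used when ``n_uas == 0``.
    """

    gene: GeneId
    n_uas: int
    coop_pairs: frozenset[tuple[int, int]] = frozenset()
    contributions: tuple[float, float, float] = (0.0, 0.0, 0.0)
    constitutive: float = 0.0

    def __post_init__(self) -> None:
        if self.n_uas < 0:
            raise ValueError("n_uas must be non-negative")
        pairs = frozenset(tuple(sorted(p)) for p in self.coop_pairs)
        object.__setattr__(self, "coop_pairs", pairs)
        for i, j in pairs:
            if not (0 <= i < j < self.n_uas):
                raise ValueError(f"cooperative pair {(i, j)} outside the "
                                 f"{self.n_uas} UAS sites")


@dataclass(frozen=True)
class OccupancyState:
    """One occupancy configuration of a promoter's UAS sites."""

    site_states: tuple[SiteState, ...]
    n4: int
    n480: int
    dG: float
    K: float
    n_coop_44: int = 0
    n_coop_8080: int = 0


def _architecture(gene, n_uas, pairs, contributions=None, constitutive=0.0):
    return PromoterArchitecture(
        gene=gene, n_uas=n_uas,
        coop_pairs=frozenset(pairs),
        contributions=tuple(contributions) if contributions else (0.0,) * 3,
        constitutive=constitutive)


def default_architectures() -> dict[GeneId, PromoterArchitecture]:
    """The six GAL promoter models.

    GAL1's three UASs lie in an in-phase helical arrangement permitting
    cooperative interactions between the adjacent pairs (0,1) and (1,2);
    GAL2's two sites form one cooperative pair.  The ancestral GAL1/3
    promoter carries the same three-site core in an anti-phase arrangement
    without cooperativity.
    """
    return {
        GeneId.GAL1: _architecture(GeneId.GAL1, 3, [(0, 1), (1, 2)],
                                   (-0.05, 21.00, -0.05)),
        GeneId.GAL2: _architecture(GeneId.GAL2, 2, [(0, 1)],
                                   (-0.01, 16.00, -0.01)),
        GeneId.GAL3: _architecture(GeneId.GAL3, 1, [], (0.14, 9.00, 0.14)),
        GeneId.GAL4: _architecture(GeneId.GAL4, 0, [], None, 0.06),
        GeneId.GAL80: _architecture(GeneId.GAL80, 1, [], (0.01, 2.00, 0.01)),
        GeneId.GAL13: _architecture(GeneId.GAL13, 3, [], (0.40, 17.70, 0.40)),
    }


def enumerate_occupancies(arch: PromoterArchitecture,
                          constants: ThermoConstants | None = None
                          ) -> list[OccupancyState]:
    """Enumerate all ``3^n_uas`` occupancy configurations.

    Energies use the all-empty configuration as reference: one ``dG_bind``
    per occupied site and one cooperative term per like-bound coop pair.
    """
    constants = constants or ThermoConstants()
    states = []
    for occ in itertools.product(SiteState, repeat=arch.n_uas):
        n4 = sum(s is SiteState.GAL4 for s in occ)
        n480 = sum(s is SiteState.GAL480 for s in occ)
        K = sum(arch.contributions[s] for s in occ) if arch.n_uas else 0.0
        c44 = sum(1 for i, j in arch.coop_pairs
                  if occ[i] is SiteState.GAL4 and occ[j] is SiteState.GAL4)
        c88 = sum(1 for i, j in arch.coop_pairs
                  if occ[i] is SiteState.GAL480 and occ[j] is SiteState.GAL480)
        dG = ((n4 + n480) * constants.dG_bind
              + c44 * constants.dG_coop_44
              + c88 * constants.dG_coop_8080)
        states.append(OccupancyState(tuple(occ), n4, n480, dG, K, c44, c88))
    return states


def promoter_propensity(arch: PromoterArchitecture,
                        conc_gal4: float,
                        conc_gal480: float,
                        constants: ThermoConstants | None = None) -> float:
    """Transcription propensity per gene copy (transcripts per second).

    ``conc_gal4`` and ``conc_gal480`` are molar nuclear concentrations of
    free Gal4p and of the Gal4-80p complex.  With no UAS the constitutive
    constant is returned regardless of concentrations.  Both concentrations
    zero is legal (only the empty configuration carries weight).
    """
    if conc_gal4 < 0 or conc_gal480 < 0:
        raise ValueError("transcription factor concentrations must be "
                         "non-negative")
    constants = constants or ThermoConstants()
    if arch.n_uas == 0:
        return arch.constitutive
    a4 = conc_gal4 / constants.tf_ref_conc
    a480 = conc_gal480 / constants.tf_ref_conc
    num = 0.0
    den = 0.0
    for st in enumerate_occupancies(arch, constants):
        w = (a4 ** st.n4) * (a480 ** st.n480) * math.exp(-st.dG / constants.beta)
        num += st.K * w
        den += w
    return max(0.0, num / den)


# ---------------------------------------------------------------------------
# packed tables for the simulation kernel

@dataclass(frozen=True)
class PackedPromoters:
    """Occupancy tables of all six promoters as flat arrays.

    Layout: for gene g, states ``offsets[g]:offsets[g+1]`` with per-state
    Gal4/Gal4-80 site counts, the contribution sum K, and the
    concentration-independent weight prefactor (cooperativity Boltzmann
    factors).  ``weight_per_molecule`` maps one free TF molecule to its
    per-site statistical weight; ``constitutive`` is used where a gene has
    no UAS (flagged by a negative state count slot being empty).
    """

    offsets: np.ndarray      # (7,) int64
    n4: np.ndarray           # (total_states,) int64
    n480: np.ndarray         # (total_states,) int64
    K: np.ndarray            # (total_states,) float64
    prefactor: np.ndarray    # (total_states,) float64
    constitutive: np.ndarray  # (6,) float64; NaN for regulated promoters
    weight_per_molecule: float


def pack_promoters(architectures: dict[GeneId, PromoterArchitecture],
                   constants: ThermoConstants) -> PackedPromoters:
    from .networks import GENE_ORDER

    offsets = [0]
    n4, n480, K, pref = [], [], [], []
    constitutive = np.full(6, np.nan)
    for gi, gene in enumerate(GENE_ORDER):
        arch = architectures[gene]
        if arch.n_uas == 0:
            constitutive[gi] = arch.constitutive
            offsets.append(offsets[-1])
            continue
        for st in enumerate_occupancies(arch, constants):
            n4.append(st.n4)
            n480.append(st.n480)
            K.append(st.K)
            coop = (st.n_coop_44 * constants.dG_coop_44
                    + st.n_coop_8080 * constants.dG_coop_8080)
            pref.append(math.exp(-coop / constants.beta))
        offsets.append(offsets[-1] + 3 ** arch.n_uas)
    return PackedPromoters(
        offsets=np.asarray(offsets, dtype=np.int64),
        n4=np.asarray(n4, dtype=np.int64),
        n480=np.asarray(n480, dtype=np.int64),
        K=np.asarray(K, dtype=np.float64),
        prefactor=np.asarray(pref, dtype=np.float64),
        constitutive=constitutive,
        weight_per_molecule=constants.site_weight_per_molecule,
    )
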