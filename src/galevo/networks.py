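"""Regulatory space of GAL network configurations.

The lineage from the pre-whole-genome-duplication (WGD) ancestor to
*S. cerevisiae* is modeled as a walk through gene copy-number space.  After
the WGD doubled every GAL gene, five parsimonious events separate the
post-WGD ancestor from the extant network: the specialization of the two
bi-functional *GAL1/3* duplicates into *GAL1* (galactokinase) and *GAL3*
(co-inducer), and the loss of the *GAL2*, *GAL4* and *GAL80* duplicates.
Every subset of the five events yields a distinct, simulatable network, for
33 configurations in total (the pre-WGD ancestor plus the 32-vertex event
hypercube), connected by 5! = 120 distinct evolutionary paths.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GeneId",
    "NetworkConfiguration",
    "EvolutionaryEvent",
    "EvolutionaryPath",
    "PRE_WGD_ANCESTOR",
    "POST_WGD_ANCESTOR",
    "S_CEREVISIAE",
    "apply_event",
    "applicable_events",
    "enumerate_configurations",
    "enumerate_paths",
    "configurations_to_tsv",
    "configurations_from_tsv",
]


class GeneId(enum.Enum):
    """The six GAL genes; GAL13 is the bi-functional ancestral *GAL1/3*."""

    GAL1 = "GAL1"
    GAL2 = "GAL2"
    GAL3 = "GAL3"
    GAL4 = "GAL4"
    GAL80 = "GAL80"
    GAL13 = "GAL1/3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical column order used for copy-number vectors and TSV output.
GENE_ORDER: tuple[GeneId, ...] = (
    GeneId.GAL1,
    GeneId.GAL2,
    GeneId.GAL3,
    GeneId.GAL4,
    GeneId.GAL80,
    GeneId.GAL13,
)


class ConfigurationError(ValueError):
    """Raised for copy-number vectors outside the modeled regulatory space."""


@dataclass(frozen=True, order=True)
class NetworkConfiguration:
    """Gene copy numbers of one GAL network variant.

    Identity is the copy-number vector alone; the two GAL1/3 copies are
    interchangeable.  Valid configurations are exactly those reachable in
    the evolutionary space: the pre-WGD ancestor, or any network obtained
    from the post-WGD ancestor by a subset of the five events.
    """

    gal1: int
    gal2: int
    gal3: int
    gal4: int
    gal80: int
    gal13: int

    def __post_init__(self) -> None:
        v = self.vector
        if any(c < 0 for c in v):
            raise ConfigurationError(f"negative copy number in {v}")
        ok = (
            self.gal1 in (0, 1)
            and self.gal3 in (0, 1)
            and self.gal13 in (0, 1, 2)
            and all(c in (1, 2) for c in (self.gal2, self.gal4, self.gal80))
        )
        family = self.gal1 + self.gal3 + self.gal13
        if not ok or family not in (1, 2):
            raise ConfigurationError(f"copy-number vector {v} is outside the "
                                     "modeled GAL regulatory space")
        if family == 1 and self.vector != (0, 1, 0, 1, 1, 1):
            raise ConfigurationError(
                f"{v}: a single GAL1/GAL3/GAL1/3 copy occurs only in the "
                "pre-WGD ancestor (0,1,0,1,1,1)")

    @property
    def vector(self) -> tuple[int, ...]:
        return (self.gal1, self.gal2, self.gal3, self.gal4, self.gal80,
                self.gal13)

    @property
    def copies(self) -> Mapping[GeneId, int]:
        return dict(zip(GENE_ORDER, self.vector))

    def copy_number(self, gene: GeneId) -> int:
        return self.copies[gene]

    @classmethod
    def from_vector(cls, vector: Iterable[int]) -> "NetworkConfiguration":
        return cls(*map(int, vector))

    @classmethod
    def from_mapping(cls, copies: Mapping[GeneId, int]) -> "NetworkConfiguration":
        return cls(*(int(copies[g]) for g in GENE_ORDER))

    @property
    def table_row(self) -> int:
        """1-based row index in the canonical configuration table.

        The canonical table lists all 33 valid configurations sorted
        lexicographically by copy-number vector; this ordering reproduces
        the numbering used for the published network variants.
        """
        return _TABLE_INDEX[self.vector]

    def __repr__(self) -> str:
        return f"NetworkConfiguration{self.vector}"


class EvolutionaryEvent(enum.Enum):
    """The five parsimonious post-WGD events."""

    SPECIALIZE_GAL1 = "SPECIALIZE_GAL1"
    SPECIALIZE_GAL3 = "SPECIALIZE_GAL3"
    LOSE_GAL2_DUP = "LOSE_GAL2_DUP"
    LOSE_GAL4_DUP = "LOSE_GAL4_DUP"
    LOSE_GAL80_DUP = "LOSE_GAL80_DUP"


class EventNotApplicable(ValueError):
    """Raised when an evolutionary event cannot occur at a configuration."""

    def __init__(self, event: EvolutionaryEvent, config: NetworkConfiguration):
        self.event = event
        self.config = config
        super().__init__(f"event {event.name} is not applicable at "
                         f"configuration {config.vector}")


PRE_WGD_ANCESTOR = NetworkConfiguration(0, 1, 0, 1, 1, 1)
POST_WGD_ANCESTOR = NetworkConfiguration(0, 2, 0, 2, 2, 2)
S_CEREVISIAE = NetworkConfiguration(1, 1, 1, 1, 1, 0)


def whole_genome_duplication(config: NetworkConfiguration) -> NetworkConfiguration:
    """Double every gene (the WGD edge; applied only to the pre-WGD ancestor)."""
    return NetworkConfiguration.from_vector(2 * c for c in config.vector)


def applicable_events(config: NetworkConfiguration) -> list[EvolutionaryEvent]:
    """Events that can occur at ``config``, in canonical enum order."""
    events = []
    if config.gal13 >= 1 and config.gal1 == 0:
        events.append(EvolutionaryEvent.SPECIALIZE_GAL1)
    if config.gal13 >= 1 and config.gal3 == 0:
        events.append(EvolutionaryEvent.SPECIALIZE_GAL3)
    if config.gal2 == 2:
        events.append(EvolutionaryEvent.LOSE_GAL2_DUP)
    if config.gal4 == 2:
        events.append(EvolutionaryEvent.LOSE_GAL4_DUP)
    if config.gal80 == 2:
        events.append(EvolutionaryEvent.LOSE_GAL80_DUP)
    return events


def apply_event(config: NetworkConfiguration,
                event: EvolutionaryEvent) -> NetworkConfiguration:
    """Apply one evolutionary event to a configuration.

    Specialization converts one GAL1/3 copy into GAL1 or GAL3; loss events
    drop a duplicate from two copies to one.  Raises
    :class:`EventNotApplicable` if the precondition fails.
    """
    if event not in applicable_events(config):
        raise EventNotApplicable(event, config)
    c = dict(config.copies)
    if event is EvolutionaryEvent.SPECIALIZE_GAL1:
        c[GeneId.GAL13] -= 1
        c[GeneId.GAL1] = 1
    elif event is EvolutionaryEvent.SPECIALIZE_GAL3:
        c[GeneId.GAL13] -= 1
        c[GeneId.GAL3] = 1
    elif event is EvolutionaryEvent.LOSE_GAL2_DUP:
        c[GeneId.GAL2] -= 1
    elif event is EvolutionaryEvent.LOSE_GAL4_DUP:
        c[GeneId.GAL4] -= 1
    else:
        c[GeneId.GAL80] -= 1
    return NetworkConfiguration.from_mapping(c)


def enumerate_configurations() -> set[NetworkConfiguration]:
    """All 33 network configurations of the modeled regulatory space.

    The pre-WGD ancestor plus every network reachable from the post-WGD
    ancestor by a subset of the five events (order never matters for the
    resulting copy-number vector).
    """
    configs = {PRE_WGD_ANCESTOR}
    events = list(EvolutionaryEvent)
    for mask in itertools.product((False, True), repeat=5):
        c = POST_WGD_ANCESTOR
        for include, ev in zip(mask, events):
            if include:
                c = apply_event(c, ev)
        configs.add(c)
    return configs


_TABLE_INDEX: dict[tuple[int, ...], int] = {}


def _build_table_index() -> None:
    ordered = sorted(enumerate_configurations(), key=lambda c: c.vector)
    for i, c in enumerate(ordered, start=1):
        _TABLE_INDEX[c.vector] = i


@dataclass(frozen=True)
class EvolutionaryPath:
    """One ordering of the five events: a walk of 7 networks.

    ``networks[0]`` is the pre-WGD ancestor, ``networks[1]`` the post-WGD
    ancestor (the WGD edge is part of every path but never scored), and
    ``networks[6]`` is *S. cerevisiae*.
    """

    event_order: tuple[EvolutionaryEvent, ...]
    networks: tuple[NetworkConfiguration, ...]

    @classmethod
    def from_events(cls, event_order: Iterable[EvolutionaryEvent]
                    ) -> "EvolutionaryPath":
        order = tuple(event_order)
        if sorted(e.name for e in order) != sorted(e.name for e in
                                                   EvolutionaryEvent):
            raise ValueError("event_order must be a permutation of the five "
                             "evolutionary events")
        networks = [PRE_WGD_ANCESTOR, POST_WGD_ANCESTOR]
        for ev in order:
            networks.append(apply_event(networks[-1], ev))
        return cls(order, tuple(networks))

    @property
    def table_rows(self) -> tuple[int, ...]:
        return tuple(n.table_row for n in self.networks)

    def event_names(self) -> list[str]:
        return [e.name for e in self.event_order]


def enumerate_paths() -> list[EvolutionaryPath]:
    """All 120 evolutionary paths (one per permutation of the five events)."""
    return [EvolutionaryPath.from_events(p)
            for p in itertools.permutations(EvolutionaryEvent)]


# ---------------------------------------------------------------------------
# serialization

def configurations_to_frame(configs: Iterable[NetworkConfiguration]
                            ) -> pd.DataFrame:
    rows = sorted(configs, key=lambda c: c.table_row)
    df = pd.DataFrame([c.vector for c in rows],
                      columns=[str(g) for g in GENE_ORDER])
    df.insert(0, "network", [c.table_row for c in rows])
    return df


def configurations_to_tsv(configs: Iterable[NetworkConfiguration],
                          path: str | Path) -> None:
    configurations_to_frame(configs).to_csv(path, sep="\t", index=False)


def configurations_from_tsv(path: str | Path) -> list[NetworkConfiguration]:
    df = pd.read_csv(path, sep="\t")
    cols = [str(g) for g in GENE_ORDER]
    return [NetworkConfiguration.from_vector(row) for row in
            df[cols].itertuples(index=False)]


def paths_to_json(paths: Iterable[EvolutionaryPath], path: str | Path) -> None:
    records = [{"events": p.event_names(), "rows": list(p.table_rows)}
               for p in paths]
    Path(path).write_text(json.dumps(records, indent=1))


_build_table_index()
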