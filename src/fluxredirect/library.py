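"""Redirection-coefficient libraries.

A library is the menu of candidate engineering instructions: entries
``(enzyme group, level, beta)`` where ``beta`` is the signed weight a
selected instruction contributes to the system objective.  Positive
``beta`` incentivizes increased flux through the group's reactions
(up-regulation); negative incentivizes decreases (down-regulation, with
knockout as the limiting case).  Three constructions are provided:

flat
    ``beta in {+1, -1}`` for every group — unbiased, one level per sign.
power series
    ``beta in {+-2^n, n <= 0}`` down to a tuning depth ``s``; several
    same-sign levels of one group may be co-selected and their betas sum,
    so the net instruction is tunable in steps of the finest level.
sensitivity
    ``beta = +-|score|`` from LP sensitivity analysis of each group on the
    growth and production objectives; groups with zero score on both are
    excluded, focusing the search on reactions that directly move either
    objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fba import LinearObjective, sensitivity_scores
from .groups import EnzymeGroup
from .network import MetabolicNetwork


@dataclass(frozen=True)
class LibraryEntry:
    group_id: str
    level_id: str
    beta: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.group_id, self.level_id)

    @property
    def sign(self) -> int:
        return 1 if self.beta > 0 else -1


@dataclass
class CoefficientLibrary:
    """Candidate redirection coefficients per enzyme group."""

    entries: list[LibraryEntry]
    groups: dict[str, EnzymeGroup] = field(default_factory=dict)
    kind: str = "flat"
    tuning_depth: int = 1

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.key in seen:
                raise ValueError(f"duplicate library entry {e.key}")
            seen.add(e.key)
            if self.groups and e.group_id not in self.groups:
                raise ValueError(f"entry references unknown group {e.group_id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, group_id: str, level_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.group_id == group_id and e.level_id == level_id:
                return e
        raise KeyError(f"no library entry ({group_id!r}, {level_id!r})")

    def by_key(self) -> dict[tuple[str, str], LibraryEntry]:
        return {e.key: e for e in self.entries}

    def group_reactions(self, group_id: str) -> tuple[str, ...]:
        return self.groups[group_id].reactions


def _index_groups(groups: list[EnzymeGroup]) -> dict[str, EnzymeGroup]:
    return {g.group_id: g for g in groups}


def build_flat_library(groups: list[EnzymeGroup]) -> CoefficientLibrary:
    """One up and one down entry per group, ``beta = +-1``."""
    entries = []
    for g in groups:
        entries.append(LibraryEntry(g.group_id, "up", 1.0))
        entries.append(LibraryEntry(g.group_id, "down", -1.0))
    return CoefficientLibrary(entries, _index_groups(groups), kind="flat", tuning_depth=1)


def build_power_series_library(groups: list[EnzymeGroup], s: int) -> CoefficientLibrary:
    """Entries ``+-2^0, +-2^-1, ..., +-2^-(s-1)`` per group.

    Same-sign levels of one group may be co-selected; their betas sum to
    the net instruction (e.g. +1 and +0.5 give a net up-regulation of 1.5).
    """
    if s < 1:
        raise ValueError("tuning depth s must be >= 1")
    entries = []
    for g in groups:
        for n in range(s):
            beta = 2.0 ** (-n)
            entries.append(LibraryEntry(g.group_id, f"up:{-n}", beta))
            entries.append(LibraryEntry(g.group_id, f"down:{-n}", -beta))
    return CoefficientLibrary(
        entries, _index_groups(groups), kind="power_series", tuning_depth=s
    )


def build_sensitivity_library(
    network: MetabolicNetwork,
    growth_objective: LinearObjective,
    production_objective: LinearObjective,
    groups: list[EnzymeGroup],
    normalize: bool = False,
) -> CoefficientLibrary:
    """Library from LP sensitivity of each group on both objectives.

    Per group the score is aggregated over member reactions as the maximum
    absolute reduced cost, taken separately on the growth and the
    production objective; the entry magnitude is the larger of the two.
    Groups scoring zero on both objectives receive no entries.  With
    ``normalize=True`` magnitudes are rescaled so the largest is 1.
    """
    growth_scores, _ = sensitivity_scores(network, growth_objective)
    prod_scores, _ = sensitivity_scores(network, production_objective)
    entries = []
    kept: dict[str, EnzymeGroup] = {}
    magnitudes: dict[str, float] = {}
    for g in groups:
        mag = 0.0
        for scores in (growth_scores, prod_scores):
            for rxn in g.reactions:
                mag = max(mag, abs(scores.get(rxn, 0.0)))
        if mag > 0.0:
            magnitudes[g.group_id] = mag
            kept[g.group_id] = g
    if normalize and magnitudes:
        top = max(magnitudes.values())
        magnitudes = {k: v / top for k, v in magnitudes.items()}
    for gid, mag in magnitudes.items():
        entries.append(LibraryEntry(gid, "up", mag))
        entries.append(LibraryEntry(gid, "down", -mag))
    return CoefficientLibrary(entries, kept, kind="sensitivity", tuning_depth=1)


def write_library_tsv(library: CoefficientLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tlevel_id\tbeta\tkind\n")
        for e in library.entries:
            fh.write(f"{e.group_id}\t{e.level_id}\t{e.beta:.6g}\t{library.kind}\n")
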