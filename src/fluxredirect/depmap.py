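"""Combinatorial interdependency analysis of a pooled target set.

Targets discovered across separate searches (different neighborhood sizes,
different coefficient libraries) are pooled and every subset up to size
``N`` is evaluated by single-level FBA of its system objective at a fixed,
weak growth parameter (``gamma = 0.02`` by default; the progressive
escalation is deliberately *not* applied here).  A subset qualifies as a
*dependency set* when it reaches at least 20% of the maximum possible
production and strictly improves on every proper subset — the minimal
combinations that form the core of production designs.  Singletons and
pairs are rendered as an undirected dependency graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .design import Design, evaluate_design
from .library import CoefficientLibrary, EnzymeGroup, LibraryEntry
from .network import MetabolicNetwork


@dataclass(frozen=True)
class PoolTarget:
    """One pooled candidate alteration: an enzyme group with a signed beta."""

    group_id: str
    sign: int  # +1 up-regulate, -1 down-regulate
    beta: float
    label: str = ""  # provenance, e.g. the library that discovered it

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.beta * self.sign <= 0:
            raise ValueError("beta must carry the stated sign")


@dataclass(frozen=True)
class DependencySet:
    """A minimal target combination that raises production."""

    members: frozenset[tuple[str, int]]  # (group_id, sign)
    production: float
    labels: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)


def _pool_library(
    pool: list[PoolTarget], groups: dict[str, EnzymeGroup]
) -> tuple[CoefficientLibrary, list[tuple[str, str]]]:
    entries = []
    keys = []
    for i, t in enumerate(pool):
        level = f"pool:{i}"
        entries.append(LibraryEntry(t.group_id, level, t.beta))
        keys.append((t.group_id, level))
    return CoefficientLibrary(entries, groups, kind="pool"), keys


def map_dependencies(
    network: MetabolicNetwork,
    target_pool: list[PoolTarget],
    n_max: int,
    export_reaction: str,
    groups: dict[str, EnzymeGroup],
    gamma: float = 0.02,
    biomass_min: float | None = None,
    min_production_fraction: float = 0.2,
    improvement_tol: float = 1e-6,
    max_production: float | None = None,
) -> list[DependencySet]:
    """All minimal qualifying target combinations up to size ``n_max``.

    Enumerates subsets of the (deduplicated, canonically sorted) pool in
    deterministic lexicographic order; subsets pairing both signs of one
    group are not valid designs and are skipped.  Each subset is evaluated
    at the given ``gamma``; it is retained iff production reaches
    ``min_production_fraction`` of the maximum possible production *and*
    strictly exceeds (by ``improvement_tol``) the production of every
    proper subset, including the empty design's baseline.  Failed LP
    evaluations skip the subset.  Output order: descending production,
    then ascending size, then member ids.
    """
    if n_max < 1:
        raise ValueError("subset size bound N must be >= 1")
    # canonical pool: dedupe identical (group, sign, beta), sort for
    # order-invariance of the enumeration
    seen = {}
    for t in target_pool:
        seen.setdefault((t.group_id, t.sign, t.beta), t)
    pool = sorted(seen.values(), key=lambda t: (t.group_id, -t.sign, t.beta))
    library, keys = _pool_library(pool, groups)

    if max_production is None:
        from .search import _max_flux

        max_production = _max_flux(network, export_reaction, biomass_min)
    floor = min_production_fraction * max_production

    baseline = evaluate_design(
        network, Design(), gamma, library, export_reaction, biomass_min
    )[1]
    production: dict[frozenset, float] = {frozenset(): baseline}
    results: list[DependencySet] = []
    for size in range(1, n_max + 1):
        for combo in itertools.combinations(range(len(pool)), size):
            sides = {}
            ok = True
            for i in combo:
                if sides.setdefault(pool[i].group_id, pool[i].sign) != pool[i].sign:
                    ok = False
                    break
            if not ok:
                continue
            idx_set = frozenset(combo)
            design = Design(frozenset(keys[i] for i in combo))
            try:
                _, prod = evaluate_design(
                    network, design, gamma, library, export_reaction, biomass_min
                )
            except Exception:
                continue
            production[idx_set] = prod
            if prod < floor:
                continue
            improves = all(
                prod > production[sub] + improvement_tol
                for r in range(size)
                for sub in map(frozenset, itertools.combinations(combo, r))
                if sub in production
            )
            if improves:
                members = frozenset((pool[i].group_id, pool[i].sign) for i in combo)
                labels = tuple(sorted({pool[i].label for i in combo if pool[i].label}))
                results.append(DependencySet(members, prod, labels))
    results.sort(key=lambda s: (-s.production, s.size, sorted(s.members)))
    return results


def dependency_graph(
    sets: list[DependencySet], max_production: float | None = None
) -> nx.Graph:
    """Undirected graph of singleton and pair dependency sets.

    Nodes are targets appearing in sets of size <= 2, attributed
    ``role="alone"`` when the target qualifies by itself and
    ``role="pair_only"`` otherwise; edges are qualifying pairs with their
    production, flagged ``high_production`` at >= 90% of
    ``max_production`` (when provided).
    """
    graph = nx.Graph()
    singles = {next(iter(s.members)) for s in sets if s.size == 1}
    for s in sets:
        if s.size > 2:
            continue
        for member in s.members:
            node = _node_name(member)
            role = "alone" if member in singles else "pair_only"
            if node not in graph or role == "alone":
                graph.add_node(node, role=role, sign=member[1])
        if s.size == 2:
            a, b = sorted(s.members)
            flagged = bool(
                max_production is not None and s.production >= 0.9 * max_production
            )
            graph.add_edge(
                _node_name(a), _node_name(b),
                production=s.production, high_production=flagged,
            )
    return graph


def _node_name(member: tuple[str, int]) -> str:
    gid, sign = member
    return f"{gid}[{'+' if sign > 0 else '-'}]"


def write_sets_tsv(sets: list[DependencySet], path) -> None:
    with open(path, "w") as fh:
        fh.write("dependency_set\tsize\tlibrary\tproduction\n")
        for s in sets:
            names = ", ".join(_node_name(m) for m in sorted(s.members))
            fh.write(f"{names}\t{s.size}\t{'/'.join(s.labels)}\t{s.production:.6g}\n")


def write_edge_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("target_a\ttarget_b\tproduction\tflagged_90pct\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{data['production']:.6g}\t{int(data['high_production'])}\n"
            )
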