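"""Toy metabolic networks with known optimal designs, and an exhaustive
design-search oracle.

The four topologies emulate, at desk scale, the structural situations a
strain-design method must handle in a genome-scale model:

``branch`` (T1)
    A substrate is split between growth and a two-step product branch —
    the basic growth-vs-production trade-off.
``linear_chain`` (T2)
    The product sits at the end of a linear chain of distinctly catalyzed
    steps drawing from the growth precursor; redirecting flux requires
    incentivizing *several* chain enzymes at once, the behavior that
    distinguishes objective-based alteration models from flux-bound ones.
``dead_end`` (T3)
    T1 plus a zero-capacity dead-end reaction whose enzyme can never
    carry flux — sensitivity-based candidate filtering must drop it.
``drain_competition`` (T4)
    A branch network in which a drain pulls the product-pathway
    intermediate back into growth metabolism, so high production needs a
    *pair* of alterations: up-regulate the branch enzyme and down-regulate
    the drain.  Neither alteration works alone.

Biomass draws the primary substrate 1:1, so maximal growth equals the
uptake bound and growth and production trade off unit for unit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .design import Design, evaluate_design
from .library import CoefficientLibrary
from .network import MetabolicNetwork

#: reaction ids shared by all toy networks
TOY_BIOMASS = "R_bio"
TOY_EXPORT = "R_exp"

_TOPOLOGY_ALIASES = {
    "T1": "branch",
    "T2": "linear_chain",
    "T3": "dead_end",
    "T4": "drain_competition",
}


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Deterministic recipe for one toy network."""

    topology: str = "branch"
    chain_length: int = 3
    uptake_bound: float = 10.0
    seed: int = 0

    def canonical_topology(self) -> str:
        topo = _TOPOLOGY_ALIASES.get(self.topology, self.topology)
        if topo not in ("branch", "linear_chain", "dead_end", "drain_competition"):
            raise ValueError(f"unknown toy topology {self.topology!r}")
        return topo


def make_toy_network(spec: ToyNetworkSpec) -> MetabolicNetwork:
    """Build the toy network described by ``spec`` (purely deterministic)."""
    topo = spec.canonical_topology()
    cap = 50.0  # loose internal cap; mass balance keeps fluxes <= uptake
    u = float(spec.uptake_bound)
    mets: list[str] = []
    rxns: list[tuple[str, dict[str, float], float, float, str]] = []

    def add(rid, stoich, lb, ub, gpr):
        rxns.append((rid, stoich, lb, ub, gpr))

    if topo in ("branch", "dead_end"):
        mets = ["A", "C", "P"]
        add("R_up", {"A": 1.0}, 0.0, u, "uptA")
        add(TOY_BIOMASS, {"A": -1.0}, 0.0, cap, "")
        add("R_ac", {"A": -1.0, "C": 1.0}, 0.0, cap, "enzB")
        add("R_cp", {"C": -1.0, "P": 1.0}, 0.0, cap, "enzP")
        add(TOY_EXPORT, {"P": -1.0}, 0.0, cap, "")
        if topo == "dead_end":
            mets.append("Q")
            add("R_dead", {"C": -1.0, "Q": 1.0}, 0.0, 0.0, "enzX")
    elif topo == "linear_chain":
        length = int(spec.chain_length)
        if length < 1:
            raise ValueError("chain_length must be >= 1")
        mets = ["A"] + [f"M{i}" for i in range(1, length + 1)]
        add("R_up", {"A": 1.0}, 0.0, u, "")
        add(TOY_BIOMASS, {"A": -1.0}, 0.0, cap, "")
        prev = "A"
        for i in range(1, length + 1):
            cur = f"M{i}"
            add(f"R_c{i}", {prev: -1.0, cur: 1.0}, 0.0, cap, f"enz{i}")
            prev = cur
        add(TOY_EXPORT, {prev: -1.0}, 0.0, cap, "")
    else:  # drain_competition
        mets = ["A", "X", "C", "P"]
        add("R_up", {"A": 1.0}, 0.0, u, "uptA")
        add("R_ax", {"A": -1.0, "X": 1.0}, 0.0, cap, "")
        add(TOY_BIOMASS, {"X": -1.0}, 0.0, cap, "")
        add("R_ac", {"A": -1.0, "C": 1.0}, 0.0, cap, "enzB")
        add("R_drain", {"C": -1.0, "X": 1.0}, 0.0, cap, "enzD")
        add("R_cp", {"C": -1.0, "P": 1.0}, 0.0, cap, "")
        add(TOY_EXPORT, {"P": -1.0}, 0.0, cap, "")

    return MetabolicNetwork(
        metabolites=mets,
        reactions=[r[0] for r in rxns],
        stoichiometry={r[0]: dict(r[1]) for r in rxns},
        lower_bound={r[0]: r[2] for r in rxns},
        upper_bound={r[0]: r[3] for r in rxns},
        gene_association={r[0]: r[4] for r in rxns},
        biomass_reaction=TOY_BIOMASS,
        name=f"toy_{topo}_{spec.chain_length}_{spec.uptake_bound:g}",
    )


#: refuse exhaustive enumeration beyond this many library entries
ORACLE_ENTRY_CAP = 24


def _sign_ok(selection: frozenset, signs: dict) -> bool:
    seen: dict[str, int] = {}
    for key in selection:
        gid = key[0]
        s = signs[key]
        if seen.setdefault(gid, s) != s:
            return False
    return True


def brute_force_design_search(
    network: MetabolicNetwork,
    library: CoefficientLibrary,
    incumbent: Design,
    k: int,
    gamma: float,
    export_reaction: str = TOY_EXPORT,
    biomass_min: float | None = None,
) -> tuple[Design, float]:
    """Exhaustive local design search: the testing oracle.

    Enumerates every selection set within symmetric-difference ``k`` of
    the incumbent that respects sign exclusivity, evaluates each by
    single-level FBA of its system objective (optimistic export
    tie-break), and returns ``(best design, production)``.  Ties are
    broken deterministically toward fewer selections, then
    lexicographically.  Refuses libraries above ``ORACLE_ENTRY_CAP``
    entries: exact by construction, exponential by nature.
    """
    if k < 1:
        raise ValueError("neighborhood size k must be >= 1")
    entries = [e.key for e in library.entries]
    if len(entries) > ORACLE_ENTRY_CAP:
        raise ValueError(
            f"{len(entries)} library entries exceed the enumeration cap "
            f"({ORACLE_ENTRY_CAP})"
        )
    signs = {e.key: e.sign for e in library.entries}
    coef_cache: dict[frozenset, float] = {}
    best: tuple[float, int, tuple] | None = None
    best_design = incumbent

    def production_of(design: Design) -> float:
        coefs = frozenset(design.reaction_coefficients(library).items())
        if coefs not in coef_cache:
            _, prod = evaluate_design(
                network, design, gamma, library, export_reaction, biomass_min
            )
            coef_cache[coefs] = prod
        return coef_cache[coefs]

    base = incumbent.selections
    for size in range(0, k + 1):
        for toggles in itertools.combinations(entries, size):
            selection = base.symmetric_difference(toggles)
            if not _sign_ok(selection, signs):
                continue
            candidate = Design(frozenset(selection))
            prod = production_of(candidate)
            # ties compared at 1e-9 resolution so LP noise cannot override
            # the deterministic smaller-design / lexicographic preference
            key = (-round(prod, 9), len(selection), tuple(sorted(selection)))
            if best is None or key < best:
                best = key
                best_design = candidate
                best_production = prod
    return best_design, best_production
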