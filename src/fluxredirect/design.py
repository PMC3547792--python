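"""Designs and the system objective.

A *design* is a set of selected library entries ``(enzyme group, level)``.
Summing the selected betas per group gives the group's net engineering
instruction, and every member reaction of a selected group carries that
net coefficient in the *system objective*

    Z_system = gamma * v_biomass + sum_j coef_j * v_j

— the compound inner objective balancing the organism's growth drive
(weighted by the progressive growth parameter ``gamma``) against the
engineered redirection incentives.  Designs are evaluated by single-level
FBA on the system objective; the redirection terms are incentives only and
never tighten any flux bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .fba import FluxState, LinearObjective, SolverError, lp_system, _flux_state
from .library import CoefficientLibrary
from .network import MetabolicNetwork


@dataclass(frozen=True)
class Design:
    """Immutable set of selected (group_id, level_id) pairs."""

    selections: frozenset[tuple[str, str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs) -> "Design":
        return cls(frozenset((str(g), str(l)) for g, l in pairs))

    def __len__(self) -> int:
        return len(self.selections)

    def sorted_selections(self) -> list[tuple[str, str]]:
        return sorted(self.selections)

    def groups(self) -> set[str]:
        return {g for g, _ in self.selections}

    def net_coefficients(self, library: CoefficientLibrary) -> dict[str, float]:
        """Net instruction per group: sum of selected betas.

        Raises if a selection is missing from the library or if one group
        is selected with both signs (a mixed up/down instruction has no
        engineering reading).
        """
        table = library.by_key()
        net: dict[str, float] = {}
        signs: dict[str, set[int]] = {}
        for key in self.sorted_selections():
            if key not in table:
                raise KeyError(f"design selection {key} not in library")
            entry = table[key]
            net[entry.group_id] = net.get(entry.group_id, 0.0) + entry.beta
            signs.setdefault(entry.group_id, set()).add(entry.sign)
        for gid, ss in signs.items():
            if len(ss) > 1:
                raise ValueError(f"group {gid!r} selected with both signs")
        return net

    def reaction_coefficients(self, library: CoefficientLibrary) -> dict[str, float]:
        """Per-reaction objective coefficients implied by the design."""
        coefs: dict[str, float] = {}
        for gid, net in self.net_coefficients(library).items():
            for rxn in library.group_reactions(gid):
                coefs[rxn] = coefs.get(rxn, 0.0) + net
        return coefs

    def distance(self, other: "Design") -> int:
        """Symmetric-difference distance (additions + removals)."""
        return len(self.selections ^ other.selections)


EMPTY_DESIGN = Design()


def assemble_system_objective(
    gamma: float,
    design: Design,
    library: CoefficientLibrary,
    network: MetabolicNetwork,
) -> LinearObjective:
    """Weights of ``Z_system``: ``gamma`` on biomass plus the design's
    per-reaction net coefficients (summed if biomass itself is targeted)."""
    if not network.biomass_reaction:
        raise ValueError("network has no biomass reaction configured")
    weights = {network.biomass_reaction: float(gamma)}
    for rxn, coef in design.reaction_coefficients(library).items():
        weights[rxn] = weights.get(rxn, 0.0) + coef
    return LinearObjective(weights=weights, sense="maximize")


def evaluate_design(
    network: MetabolicNetwork,
    design: Design,
    gamma: float,
    library: CoefficientLibrary,
    export_reaction: str,
    biomass_min: float | None = None,
    opt_tol: float = 1e-9,
) -> tuple[FluxState, float]:
    """Single-level FBA of the system objective, reporting export flux.

    Among alternate optima of the system objective the reported state is
    the one maximizing product export (optimistic tie-break): a second LP
    maximizes the export flux subject to the system objective staying
    within ``opt_tol`` of its optimum.  ``biomass_min`` optionally imposes
    an absolute floor on the biomass flux (e.g. 20% of maximal growth).
    """
    objective = assemble_system_objective(gamma, design, library, network)
    system = lp_system(network)
    c = objective.vector(network)
    lb = ub = None
    if biomass_min is not None:
        lb = system.lb.copy()
        j_bio = system.index[network.biomass_reaction]
        lb[j_bio] = max(lb[j_bio], float(biomass_min))
    res = system.solve(c, "maximize", lb=lb, ub=ub)
    if res.status != 0:
        raise SolverError(f"system objective LP failed: status {res.status}")
    z_opt = -res.fun
    j_exp = system.index[export_reaction]
    c2 = np.zeros(len(network.reactions))
    c2[j_exp] = 1.0
    res2 = system.solve(
        c2,
        "maximize",
        extra_A=sparse.csr_matrix(c),
        extra_lb=np.array([z_opt - opt_tol - 1e-12 * max(1.0, abs(z_opt))]),
        lb=lb,
        ub=ub,
    )
    if res2.status != 0:  # numerically tight anchor; fall back to first state
        state = _flux_state(network, res, "maximize")
        return state, float(state.flux[export_reaction])
    state = _flux_state(network, res2, "maximize")
    state.objective_value = float(z_opt)
    return state, float(res2.x[j_exp])


def flux_change_report(
    network: MetabolicNetwork,
    design: Design,
    gamma: float,
    library: CoefficientLibrary,
    export_reaction: str,
    biomass_min: float | None = None,
    change_tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-group flux changes of a design relative to optimal growth.

    The reference state is the empty design at ``gamma = 1`` (pure growth
    optimum); the current state is the design at its ``gamma``.  For each
    selected group the report gives the summed flux change over member
    reactions and counts of members that decreased / did not change /
    increased, using a relative threshold ``change_tol * max(1, |v_ref|)``.
    A biomass row is included first.
    """
    ref_state, _ = evaluate_design(
        network, EMPTY_DESIGN, 1.0, library, export_reaction, biomass_min
    )
    cur_state, _ = evaluate_design(
        network, design, gamma, library, export_reaction, biomass_min
    )
    net = design.net_coefficients(library)

    def row(name: str, coef: float, rxns) -> dict:
        total = 0.0
        dec = nc = inc = 0
        for rxn in rxns:
            v0 = ref_state.flux[rxn]
            v1 = cur_state.flux[rxn]
            delta = v1 - v0
            total += delta
            if abs(delta) <= change_tol * max(1.0, abs(v0)):
                nc += 1
            elif delta > 0:
                inc += 1
            else:
                dec += 1
        return {
            "enzyme": name,
            "net_coefficient": coef,
            "total_flux_change": total,
            "n_decreased": dec,
            "n_unchanged": nc,
            "n_increased": inc,
        }

    rows = [row("biomass", gamma, [network.biomass_reaction])]
    group_rows = [row(gid, net[gid], library.group_reactions(gid)) for gid in net]
    group_rows.sort(key=lambda r: -r["total_flux_change"])
    return pd.DataFrame(rows + group_rows)


def write_design_tsv(design: Design, library: CoefficientLibrary, path) -> None:
    net = design.net_coefficients(library)
    table = library.by_key()
    with open(path, "w") as fh:
        fh.write("group_id\tlevel_id\tbeta\tnet_coefficient\n")
        for gid, lid in design.sorted_selections():
            e = table[(gid, lid)]
            fh.write(f"{gid}\t{lid}\t{e.beta:.6g}\t{net[gid]:.6g}\n")
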