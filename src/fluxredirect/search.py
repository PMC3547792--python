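"""Iterative local search with progressive target discovery.

The driver alternates two moves.  A *bilevel step* finds the best design
within neighborhood size ``k`` of the incumbent at the current progressive
growth parameter ``gamma``.  A *progressive step* then escalates ``gamma``
just past the strength of the incumbent's redirection function,

    gamma_new = sum_included beta_jl * (v_j - v_j_maxgrowth) / g_max + delta,

so that the growth term once again dominates the system objective and
further targets must be recruited to re-establish production.  Here
``g_max`` is the maximal biomass flux: the redirection strength is
expressed per unit of attainable growth objective, which makes the
escalation scale-free when biomass and redirection fluxes live on
different magnitudes (for genome-scale models with ``g_max`` near 1 the
division is a no-op).  ``delta`` is a small increment whose only role is
strictness; results are invariant to it across orders of magnitude.

Whether to continue, escalate, checkpoint or stop after an iteration
follows a four-branch decision rule on (production fraction, new targets
found); checkpoints record designs achieving the production threshold and
the final design is the checkpoint with the highest ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bilevel import solve_bilevel
from .design import EMPTY_DESIGN, Design, evaluate_design
from .fba import FluxState, LinearObjective, SolverError, lp_system
from .groups import derive_enzyme_groups
from .library import (
    CoefficientLibrary,
    build_flat_library,
    build_power_series_library,
    build_sensitivity_library,
)
from .network import MetabolicNetwork

import numpy as np


@dataclass
class SearchConfig:
    """Tunable parameters of the progressive search."""

    k: int = 1
    max_iterations: int = 30
    library_kind: str = "flat"  # flat | power_series | sensitivity
    tuning_depth: int = 2  # power-series levels per sign
    production_threshold: float = 0.8
    delta_progress: float = 1e-4
    gamma_initial: float = 0.02
    biomass_floor: float = 0.0  # fraction of max growth; 0 disables
    time_limit: float = 3600.0  # seconds per bilevel MILP
    seed: int = 0  # recorded for provenance; HiGHS runs deterministically

    def __post_init__(self) -> None:
        if not (0.0 < self.production_threshold <= 1.0):
            raise ValueError("production_threshold must be in (0, 1]")
        if self.delta_progress <= 0:
            raise ValueError("delta_progress must be positive")


@dataclass
class SearchState:
    """Mutable state carried across search iterations."""

    incumbent: Design = EMPTY_DESIGN
    gamma: float = 0.02
    iteration: int = 0
    production_fraction: float = 0.0
    new_targets_found: bool = False
    saved_designs: list[tuple[Design, float, float]] = field(default_factory=list)
    max_growth_fluxes: dict[str, float] = field(default_factory=dict)
    biomass_scale: float = 1.0
    max_production: float = 0.0


def decision_step(production_fraction: float, new_targets_found: bool,
                  threshold: float = 0.8) -> str:
    """Four-branch decision rule driving the search loop.

    ========================  ==================  ====================
    production vs threshold   new targets found   action
    ========================  ==================  ====================
    below                     yes                 continue
    at or above               no                  increase_gamma
    at or above               yes                 save_and_increase
    below                     no                  terminate
    ========================  ==================  ====================
    """
    high = production_fraction >= threshold
    if high and new_targets_found:
        return "save_and_increase"
    if high:
        return "increase_gamma"
    if new_targets_found:
        return "continue"
    return "terminate"


def update_progressive_growth(
    design: Design,
    design_fluxes: FluxState,
    library: CoefficientLibrary,
    max_growth_fluxes: dict[str, float],
    delta_progress: float,
    biomass_scale: float = 1.0,
) -> float:
    """New progressive growth parameter from the incumbent's redirection strength.

    Sums ``beta * (v_j - v_j_maxgrowth)`` over every included (reaction,
    level) term, divides by ``biomass_scale`` (the maximal biomass flux;
    keep 1.0 to work on the raw objective scale) and adds
    ``delta_progress``.  The caller only adopts the value if it exceeds
    the current ``gamma``.
    """
    table = library.by_key()
    strength = 0.0
    for key in design.selections:
        entry = table[key]
        for rxn in library.group_reactions(entry.group_id):
            strength += entry.beta * (
                design_fluxes.flux[rxn] - max_growth_fluxes.get(rxn, 0.0)
            )
    return strength / biomass_scale + delta_progress


def build_library(
    network: MetabolicNetwork, export_reaction: str, config: SearchConfig
) -> CoefficientLibrary:
    """Construct the coefficient library named by ``config.library_kind``."""
    groups = derive_enzyme_groups(network)
    if config.library_kind == "flat":
        return build_flat_library(groups)
    if config.library_kind == "power_series":
        return build_power_series_library(groups, config.tuning_depth)
    if config.library_kind == "sensitivity":
        growth = LinearObjective({network.biomass_reaction: 1.0})
        prod = LinearObjective({export_reaction: 1.0})
        return build_sensitivity_library(network, growth, prod, groups)
    raise ValueError(f"unknown library kind {config.library_kind!r}")


def _max_flux(network: MetabolicNetwork, reaction: str,
              biomass_min: float | None = None) -> float:
    system = lp_system(network)
    c = np.zeros(len(network.reactions))
    c[system.index[reaction]] = 1.0
    lb = None
    if biomass_min is not None:
        lb = system.lb.copy()
        lb[system.index[network.biomass_reaction]] = max(
            lb[system.index[network.biomass_reaction]], biomass_min
        )
    res = system.solve(c, "maximize", lb=lb)
    if res.status != 0:
        raise SolverError(f"cannot maximize {reaction!r}: status {res.status}")
    return float(-res.fun)


@dataclass
class SearchResult:
    design: Design
    gamma: float
    production: float
    history: pd.DataFrame
    state: SearchState


def run_progressive_search(
    network: MetabolicNetwork,
    export_reaction: str,
    config: SearchConfig,
    library: CoefficientLibrary | None = None,
) -> SearchResult:
    """Full progressive search for one product.

    The network must already contain the product-export reaction.  Loops
    bilevel optimization -> evaluation -> decision -> (optional) gamma
    escalation until termination or ``config.max_iterations``; the final
    design is the saved checkpoint with the highest ``gamma`` (or the
    incumbent when nothing was ever saved).  The per-iteration history
    (targets, gamma, production, action, solver status) is always
    returned, including after solver failures.
    """
    if library is None:
        library = build_library(network, export_reaction, config)

    g_max = _max_flux(network, network.biomass_reaction)
    biomass_min = config.biomass_floor * g_max if config.biomass_floor > 0 else None
    max_production = _max_flux(network, export_reaction, biomass_min)
    ref_state, _ = evaluate_design(
        network, EMPTY_DESIGN, 1.0, library, export_reaction, biomass_min
    )

    state = SearchState(
        gamma=config.gamma_initial,
        max_growth_fluxes=dict(ref_state.flux),
        biomass_scale=g_max if g_max > 0 else 1.0,
        max_production=max_production,
    )
    rows = []
    for it in range(config.max_iterations):
        state.iteration = it
        result = solve_bilevel(
            network,
            library,
            state.incumbent,
            config.k,
            state.gamma,
            export_reaction,
            biomass_min,
            time_limit=config.time_limit,
        )
        design = result.design
        fluxes, production = evaluate_design(
            network, design, state.gamma, library, export_reaction, biomass_min
        )
        state.new_targets_found = design.selections != state.incumbent.selections
        state.production_fraction = (
            production / max_production if max_production > 0 else 0.0
        )
        state.incumbent = design
        action = decision_step(
            state.production_fraction, state.new_targets_found,
            config.production_threshold,
        )
        rows.append(
            {
                "iteration": it,
                "n_targets": len(design),
                "gamma": state.gamma,
                "production": production,
                "production_fraction": state.production_fraction,
                "new_targets": state.new_targets_found,
                "action": action,
                "solver_status": result.status,
            }
        )
        if action == "terminate":
            break
        if action in ("increase_gamma", "save_and_increase"):
            if action == "save_and_increase":
                state.saved_designs.append((design, state.gamma, production))
            gamma_new = update_progressive_growth(
                design, fluxes, library, state.max_growth_fluxes,
                config.delta_progress, state.biomass_scale,
            )
            state.gamma = max(state.gamma, gamma_new)

    history = pd.DataFrame(
        rows,
        columns=[
            "iteration", "n_targets", "gamma", "production",
            "production_fraction", "new_targets", "action", "solver_status",
        ],
    )
    if state.saved_designs:
        final, gamma, production = state.saved_designs[-1]  # gammas are non-decreasing
    else:
        final, gamma = state.incumbent, state.gamma
        production = (
            evaluate_design(network, final, gamma, library, export_reaction, biomass_min)[1]
            if config.max_iterations > 0
            else 0.0
        )
    return SearchResult(final, gamma, production, history, state)
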