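"""Linear-programming primitives for constraint-based analysis.

All LPs are steady-state flux problems:  optimize ``c.v`` subject to
``S.v = 0`` and ``lb <= v <= ub``.  The backend is HiGHS through
:func:`scipy.optimize.linprog`, which is deterministic in single-thread
operation and exposes the dual solution needed for sensitivity scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .network import MetabolicNetwork

#: feasibility/optimality tolerance used for toy models; genome-scale
#: models should relax this to ~1e-6.
FEAS_TOL = 1e-9


class SolverError(RuntimeError):
    """Raised when an LP that is required to be solvable is not."""


@dataclass
class LinearObjective:
    """Linear flux objective: ``sense``-imize ``sum_j weights[j] * v_j``."""

    weights: dict[str, float]
    sense: str = "maximize"

    def __post_init__(self) -> None:
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"unknown sense {self.sense!r}")

    def vector(self, network: MetabolicNetwork) -> np.ndarray:
        idx = network.reaction_index()
        c = np.zeros(len(network.reactions))
        for rxn, w in self.weights.items():
            if rxn not in idx:
                raise KeyError(f"objective references unknown reaction {rxn!r}")
            c[idx[rxn]] = float(w)
        return c


@dataclass
class FluxState:
    """Solution of one flux LP."""

    flux: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class VariabilityBounds:
    """Per-reaction flux ranges under an anchored optimum."""

    bounds: dict[str, tuple[float, float]]
    anchor: str = ""
    fraction: float = 0.0


@dataclass
class _LPSystem:
    """Prebuilt arrays for repeated LP solves on one network."""

    network: MetabolicNetwork
    S: sparse.csr_matrix = field(init=False)
    lb: np.ndarray = field(init=False)
    ub: np.ndarray = field(init=False)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.S = self.network.smatrix()
        self.lb, self.ub = self.network.bounds_arrays()
        self.index = self.network.reaction_index()

    def solve(
        self,
        c: np.ndarray,
        sense: str = "maximize",
        extra_A: sparse.csr_matrix | None = None,
        extra_lb: np.ndarray | None = None,
        lb: np.ndarray | None = None,
        ub: np.ndarray | None = None,
    ):
        """Solve ``sense``-imize ``c.v`` s.t. ``S.v = 0``, bounds, and
        optionally ``extra_A.v >= extra_lb``.  Returns the raw scipy result
        (in minimization form: flip sign of ``fun`` for maximization)."""
        sign = -1.0 if sense == "maximize" else 1.0
        lo = self.lb if lb is None else lb
        hi = self.ub if ub is None else ub
        kwargs = {}
        if extra_A is not None:
            kwargs["A_ub"] = -extra_A
            kwargs["b_ub"] = -np.asarray(extra_lb, dtype=float)
        res = linprog(
            sign * c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lo, hi]),
            method="highs",
            **kwargs,
        )
        return res


_SYSTEMS: dict[int, _LPSystem] = {}


def lp_system(network: MetabolicNetwork) -> _LPSystem:
    """Memoized LP scaffold per network object (keyed by identity)."""
    key = id(network)
    system = _SYSTEMS.get(key)
    if system is None or system.network is not network:
        system = _LPSystem(network)
        _SYSTEMS[key] = system
        if len(_SYSTEMS) > 256:  # bound the cache; cheap to rebuild
            _SYSTEMS.pop(next(iter(_SYSTEMS)))
    return system


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _flux_state(network: MetabolicNetwork, res, sense: str) -> FluxState:
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxState(flux={}, objective_value=float("nan"), status=status)
    obj = -res.fun if sense == "maximize" else res.fun
    flux = {r: float(v) for r, v in zip(network.reactions, res.x)}
    return FluxState(flux=flux, objective_value=float(obj), status="optimal")


def solve_fba(network: MetabolicNetwork, objective: LinearObjective) -> FluxState:
    """Flux balance analysis: one LP, returning the solver's optimal vertex.

    Deterministic for a fixed model ordering; alternate optima are resolved
    by the solver's pivoting, so contracts that depend on a unique flux
    value must impose their own tie-break (see
    :func:`fluxredirect.design.evaluate_design`).
    """
    system = lp_system(network)
    res = system.solve(objective.vector(network), objective.sense)
    return _flux_state(network, res, objective.sense)


def flux_variability(
    network: MetabolicNetwork,
    anchor_objective: LinearObjective,
    fraction: float,
    reactions: list[str] | None = None,
) -> VariabilityBounds:
    """Min/max flux per reaction while the anchor keeps ``fraction`` of its optimum.

    Runs 2|J| LPs with the additional constraint
    ``anchor_flux >= fraction * optimal_anchor`` (``<=`` for a minimizing
    anchor).  ``fraction=0`` reduces to unconstrained per-reaction ranges.
    """
    system = lp_system(network)
    anchor_c = anchor_objective.vector(network)
    res = system.solve(anchor_c, anchor_objective.sense)
    if res.status != 0:
        raise SolverError(f"anchor objective not solvable: status {res.status}")
    opt = -res.fun if anchor_objective.sense == "maximize" else res.fun
    if anchor_objective.sense == "maximize":
        extra_A = sparse.csr_matrix(anchor_c)
        extra_lb = np.array([fraction * opt])
    else:
        extra_A = sparse.csr_matrix(-anchor_c)
        extra_lb = np.array([-fraction * opt])
    targets = reactions if reactions is not None else network.reactions
    out: dict[str, tuple[float, float]] = {}
    n = len(network.reactions)
    for rxn in targets:
        j = system.index[rxn]
        c = np.zeros(n)
        c[j] = 1.0
        lo = system.solve(c, "minimize", extra_A, extra_lb)
        hi = system.solve(c, "maximize", extra_A, extra_lb)
        if lo.status != 0 or hi.status != 0:
            raise SolverError(f"variability LP failed for {rxn!r}")
        out[rxn] = (float(lo.x[j]), float(hi.x[j]))
    anchor_name = ",".join(sorted(anchor_objective.weights))
    return VariabilityBounds(bounds=out, anchor=anchor_name, fraction=fraction)


def classify_boundary_targets(
    growth_bounds: VariabilityBounds, production_bounds: VariabilityBounds
) -> dict[str, str]:
    """Classify reactions by comparing anchored flux ranges.

    ``up``   — the production-anchored range lies strictly above the
    growth-anchored range (the flux *must* increase to produce);
    ``down`` — strictly below; ``overlap`` — the ranges intersect, i.e. the
    flux bound carries no engineering signal.
    """
    g = growth_bounds.bounds
    p = production_bounds.bounds
    if set(g) != set(p):
        raise ValueError("growth and production bounds cover different reactions")
    labels: dict[str, str] = {}
    for rxn in g:
        gmin, gmax = g[rxn]
        pmin, pmax = p[rxn]
        if pmin > gmax:
            labels[rxn] = "up"
        elif pmax < gmin:
            labels[rxn] = "down"
        else:
            labels[rxn] = "overlap"
    return labels


def sensitivity_scores(
    network: MetabolicNetwork,
    objective: LinearObjective,
    method: str = "dual",
    epsilon: float = 1e-3,
) -> tuple[dict[str, float], bool]:
    """Marginal effect of each reaction flux on the optimal objective.

    ``score_j`` is the change in the optimal objective value per unit
    forced change of ``v_j`` at the optimum: the LP reduced cost of
    reaction ``j`` (zero for basic reactions).  ``method="dual"`` reads it
    from one dual solution; ``method="finite_difference"`` re-solves with
    ``v_j`` pinned at ``v*_j +- epsilon`` (central where feasible).
    Reactions with ``lb == ub`` score 0 by contract — their flux cannot be
    engineered.

    Returns ``(scores, degenerate)``.  When the LP has alternate dual
    solutions the dual-based scores come from the one vertex the solver
    returned; ``degenerate`` flags that situation.
    """
    system = lp_system(network)
    c = objective.vector(network)
    if objective.sense == "minimize":
        c = -c  # score convention below is for maximization
    res = system.solve(c, "maximize")
    if res.status != 0:
        raise SolverError(f"objective not solvable: status {res.status}")
    n = len(network.reactions)
    fixed = system.lb == system.ub

    if method == "finite_difference":
        # Pin v_j at v*_j +- eps and re-solve.  Central difference where
        # both probes are feasible.  A probe blocked by the reaction's own
        # bound leaves a one-sided slope (the reduced cost of a nonbasic
        # variable at that bound); a probe inside the bounds but made
        # infeasible by the rest of the network means the two-sided
        # marginal does not exist and the score is 0 — the network, not
        # the engineerable bound, pins the flux there.
        scores_fd: dict[str, float] = {}
        for j, rxn in enumerate(network.reactions):
            if fixed[j]:
                scores_fd[rxn] = 0.0
                continue
            vals: dict[float, float] = {}
            blocked_by_network = False
            for direction in (+1.0, -1.0):
                target = res.x[j] + direction * epsilon
                if target < system.lb[j] - FEAS_TOL or target > system.ub[j] + FEAS_TOL:
                    continue  # own bound: one-sided slope is meaningful
                lb2, ub2 = system.lb.copy(), system.ub.copy()
                lb2[j] = ub2[j] = target
                pert = system.solve(c, "maximize", lb=lb2, ub=ub2)
                if pert.status == 0:
                    vals[direction] = -pert.fun
                else:
                    blocked_by_network = True
            base = -res.fun
            if len(vals) == 2:
                scores_fd[rxn] = (vals[1.0] - vals[-1.0]) / (2 * epsilon)
            elif blocked_by_network or not vals:
                scores_fd[rxn] = 0.0
            elif 1.0 in vals:
                scores_fd[rxn] = (vals[1.0] - base) / epsilon
            else:
                scores_fd[rxn] = (base - vals[-1.0]) / epsilon
        return scores_fd, False

    if method != "dual":
        raise ValueError(f"unknown sensitivity method {method!r}")

    # reduced cost in max convention: z_j = c_j + m . S_j with m the
    # equality duals of the minimization form returned by HiGHS.
    m = np.asarray(res.eqlin.marginals)
    z = c + system.S.T.dot(m)
    z[fixed] = 0.0
    z[np.abs(z) < 1e-11] = 0.0
    # dual degeneracy: a variable strictly between bounds normally has
    # zero reduced cost; a zero reduced cost *at* a bound signals
    # alternate optima and therefore alternate dual vertices.
    at_bound = (np.abs(res.x - system.lb) < 1e-9) | (np.abs(res.x - system.ub) < 1e-9)
    degenerate = bool(np.any(at_bound & (z == 0.0) & ~fixed))
    return {r: float(z[j]) for j, r in enumerate(network.reactions)}, degenerate
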