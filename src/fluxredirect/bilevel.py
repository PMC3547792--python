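"""Bilevel target selection as a single mixed-integer linear program.

The outer problem chooses a set of library entries (binaries ``y``) within
a neighborhood of an incumbent design so as to maximize product export;
the inner problem is the cell's FBA response: flux ``v`` must be optimal
for the system objective induced by ``y``.  Inner optimality is certified
inside the MILP by LP duality — primal feasibility, dual feasibility and
the strong-duality equality — with the bilinear products ``y * v``
replaced by inclusion variables ``w`` under a big-M linearization
(``w_e_j = v_j`` when entry ``e`` is selected, else 0).  Because the inner
objective is *linear in y*, the dual-feasibility rows need no
linearization at all; only the ``w`` terms of the strong-duality row do.

Solved with HiGHS via :func:`scipy.optimize.milp` (deterministic,
single-threaded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .design import Design, evaluate_design
from .library import CoefficientLibrary
from .network import MetabolicNetwork


@dataclass
class BilevelResult:
    design: Design
    production: float
    status: str = "optimal"  # optimal | timeout | no_improvement
    timed_out: bool = False


def solve_bilevel(
    network: MetabolicNetwork,
    library: CoefficientLibrary,
    incumbent: Design,
    k: int,
    gamma: float,
    export_reaction: str,
    biomass_min: float | None = None,
    time_limit: float = 3600.0,
    big_m_safety: float = 1.05,
    gap_tol: float = 1e-6,
) -> BilevelResult:
    """Best design within symmetric-difference ``k`` of the incumbent.

    Additions and removals both count toward ``k``, so the search can
    backtrack out of previously chosen targets.  The returned design's
    production is recomputed by plain :func:`evaluate_design` (optimistic
    tie-break), and if it does not strictly improve on the incumbent's
    production the incumbent is returned unchanged (``status
    "no_improvement"``) — the search has exhausted this neighborhood.

    On solver timeout the best feasible design found is returned with
    ``timed_out=True``; with no feasible incumbent solution at all, the
    incumbent design is returned.
    """
    if k < 1:
        raise ValueError("neighborhood size k must be >= 1")
    entry_keys = {e.key for e in library.entries}
    missing = incumbent.selections - entry_keys
    if missing:
        raise KeyError(f"incumbent selections not in library: {sorted(missing)}")

    S = network.smatrix().tocsc()
    n = len(network.reactions)
    m = len(network.metabolites)
    ridx = network.reaction_index()
    lb, ub = network.bounds_arrays()
    if biomass_min is not None:
        jb = ridx[network.biomass_reaction]
        lb = lb.copy()
        lb[jb] = max(lb[jb], float(biomass_min))
    j_bio = ridx[network.biomass_reaction]
    j_exp = ridx[export_reaction]
    big_m = big_m_safety * np.maximum(np.abs(lb), np.abs(ub))
    big_m = np.maximum(big_m, 1.0)

    entries = list(library.entries)
    n_e = len(entries)
    # member (entry, reaction) pairs carrying a w variable
    pairs: list[tuple[int, int]] = []
    for ei, e in enumerate(entries):
        for rxn in library.group_reactions(e.group_id):
            pairs.append((ei, ridx[rxn]))
    n_w = len(pairs)

    # variable layout: v | y | w | u | mu_ub | mu_lb
    off_v, off_y, off_w = 0, n, n + n_e
    off_u, off_mu, off_ml = n + n_e + n_w, n + n_e + n_w + m, n + n_e + n_w + m + n
    n_var = off_ml + n

    rows_A, rows_lo, rows_hi = [], [], []

    def add_rows(A: sparse.coo_matrix, lo, hi):
        rows_A.append(A)
        rows_lo.append(np.atleast_1d(lo).astype(float))
        rows_hi.append(np.atleast_1d(hi).astype(float))

    def coo(triples, nrows):
        r, c, d = zip(*triples) if triples else ((), (), ())
        return sparse.coo_matrix((d, (r, c)), shape=(nrows, n_var))

    # 1. steady state S v = 0
    Sc = S.tocoo()
    add_rows(
        coo(list(zip(Sc.row, Sc.col + off_v, Sc.data)), m), np.zeros(m), np.zeros(m)
    )

    # 2. dual feasibility:  S^T u + mu_ub - mu_lb - sum_e beta_e y_e [j in g_e]
    #    = gamma * 1[j = biomass]
    triples = []
    St = S.T.tocoo()  # n x m
    triples += list(zip(St.row, St.col + off_u, St.data))
    triples += [(j, off_mu + j, 1.0) for j in range(n)]
    triples += [(j, off_ml + j, -1.0) for j in range(n)]
    for (ei, j) in pairs:
        triples.append((j, off_y + ei, -entries[ei].beta))
    rhs = np.zeros(n)
    rhs[j_bio] = gamma
    add_rows(coo(triples, n), rhs, rhs)

    # 3. strong duality: gamma v_bio + sum beta_e w_ej - ub.mu_ub + lb.mu_lb = 0
    triples = [(0, off_v + j_bio, gamma)]
    for wi, (ei, _j) in enumerate(pairs):
        triples.append((0, off_w + wi, entries[ei].beta))
    for j in range(n):
        triples.append((0, off_mu + j, -ub[j]))
        triples.append((0, off_ml + j, lb[j]))
    # The band must stay well below the smallest meaningful objective
    # difference between competing designs (set by delta_progress during
    # the search), so it is absolute, not scaled by big-M magnitudes.
    add_rows(coo(triples, 1), -gap_tol, gap_tol)

    # 4. big-M linearization of w_ej = y_e * v_j
    triples = []
    lo4 = np.empty(4 * n_w)
    hi4 = np.empty(4 * n_w)
    for wi, (ei, j) in enumerate(pairs):
        M = big_m[j]
        r = 4 * wi
        # w - M y <= 0
        triples += [(r, off_w + wi, 1.0), (r, off_y + ei, -M)]
        lo4[r], hi4[r] = -np.inf, 0.0
        # -w - M y <= 0
        triples += [(r + 1, off_w + wi, -1.0), (r + 1, off_y + ei, -M)]
        lo4[r + 1], hi4[r + 1] = -np.inf, 0.0
        # w - v + M y <= M
        triples += [(r + 2, off_w + wi, 1.0), (r + 2, off_v + j, -1.0), (r + 2, off_y + ei, M)]
        lo4[r + 2], hi4[r + 2] = -np.inf, M
        # v - w + M y <= M
        triples += [(r + 3, off_v + j, 1.0), (r + 3, off_w + wi, -1.0), (r + 3, off_y + ei, M)]
        lo4[r + 3], hi4[r + 3] = -np.inf, M
    add_rows(coo(triples, 4 * n_w), lo4, hi4)

    # 5. sign exclusivity: a group is up- or down-regulated, never both
    triples = []
    excl = 0
    by_group: dict[str, dict[int, list[int]]] = {}
    for ei, e in enumerate(entries):
        by_group.setdefault(e.group_id, {}).setdefault(e.sign, []).append(ei)
    for gid, sides in by_group.items():
        for up in sides.get(1, []):
            for dn in sides.get(-1, []):
                triples += [(excl, off_y + up, 1.0), (excl, off_y + dn, 1.0)]
                excl += 1
    if excl:
        add_rows(coo(triples, excl), np.full(excl, -np.inf), np.ones(excl))

    # 6. neighborhood: |y XOR incumbent| <= k
    inc = {key: True for key in incumbent.selections}
    triples = []
    n_inc = 0
    for ei, e in enumerate(entries):
        if e.key in inc:
            triples.append((0, off_y + ei, -1.0))
            n_inc += 1
        else:
            triples.append((0, off_y + ei, 1.0))
    add_rows(coo(triples, 1), -np.inf, float(k - n_inc))

    A = sparse.vstack(rows_A, format="csc")
    lo = np.concatenate(rows_lo)
    hi = np.concatenate(rows_hi)

    # Duals are boxed at a magnitude far above any optimal basis of these
    # LPs; unbounded free columns destabilize the MIP solver.
    dual_cap = 1e4 * max(1.0, abs(gamma), max(abs(e.beta) for e in entries))
    var_lo = np.full(n_var, -dual_cap)
    var_hi = np.full(n_var, dual_cap)
    var_lo[off_v : off_v + n] = lb
    var_hi[off_v : off_v + n] = ub
    var_lo[off_y : off_y + n_e] = 0.0
    var_hi[off_y : off_y + n_e] = 1.0
    for wi, (_ei, j) in enumerate(pairs):
        var_lo[off_w + wi] = -big_m[j]
        var_hi[off_w + wi] = big_m[j]
    var_lo[off_mu:off_ml] = 0.0  # mu_ub >= 0
    var_lo[off_ml:] = 0.0  # mu_lb >= 0

    integrality = np.zeros(n_var)
    integrality[off_y : off_y + n_e] = 1

    c = np.zeros(n_var)
    c[off_v + j_exp] = -1.0  # maximize export

    # HiGHS occasionally reports a solve error on the narrow
    # strong-duality band with one presolve setting but not the other;
    # retry deterministically with presolve flipped before giving up.
    res = None
    for presolve in (True, False):
        res = milp(
            c,
            constraints=LinearConstraint(A, lo, hi),
            integrality=integrality,
            bounds=Bounds(var_lo, var_hi),
            options={"time_limit": float(time_limit), "mip_rel_gap": 0.0,
                     "presolve": presolve},
        )
        if res.status in (0, 1):  # solved, or hit the time limit
            break

    timed_out = res.status == 1
    if res.x is None:
        inc_prod = evaluate_design(
            network, incumbent, gamma, library, export_reaction, biomass_min
        )[1]
        return BilevelResult(incumbent, inc_prod, "timeout" if timed_out else "infeasible", timed_out)

    y = res.x[off_y : off_y + n_e]
    selection = frozenset(entries[ei].key for ei in range(n_e) if y[ei] > 0.5)
    candidate = Design(selection)
    _, cand_prod = evaluate_design(
        network, candidate, gamma, library, export_reaction, biomass_min
    )
    _, inc_prod = evaluate_design(
        network, incumbent, gamma, library, export_reaction, biomass_min
    )
    if cand_prod <= inc_prod + 1e-9:
        return BilevelResult(incumbent, inc_prod, "no_improvement", timed_out)
    return BilevelResult(candidate, cand_prod, "timeout" if timed_out else "optimal", timed_out)
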