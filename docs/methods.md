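# Methods

## The model of a metabolic alteration

Constraint-based strain design usually encodes an engineering
intervention as a change to flux *bounds*: a knockout pins a flux to
zero, an up-regulation raises a lower bound.  That encoding is awkward
whenever one enzyme catalyzes many reactions (all members would receive
the same hard constraint) and it makes interventions combine poorly,
because a set of bounds is only as effective as its tightest member.

`fluxredirect` instead models an alteration as a *term in the FBA
objective*.  The cell's inner optimization problem becomes

    maximize   Z_system = gamma * v_biomass + sum_j c_j * v_j
    subject to S v = 0,  lb <= v <= ub

where `c_j` is the net *redirection coefficient* of reaction `j` —
positive for an up-regulation incentive, negative for down-regulation —
and `gamma >= 0` weights the organism's native growth drive.  The key
property is that coefficients *incentivize but never force* flux: every
returned state satisfies only the original network bounds.  Reactions
catalyzed by the same enzyme (identical canonicalized gene association)
form one *enzyme group* and always carry the same coefficient; a group's
member fluxes may still respond in different directions, because only the
network decides how the incentive is realized.

Candidate coefficients come from a *library*:

| kind | betas | levels per sign | notes |
|---|---|---|---|
| flat | +-1 | 1 | unbiased, every group |
| power series | +-2^n, n = 0..-(s-1) | s | same-sign levels co-selectable; betas sum |
| sensitivity | +-max member reduced cost | 1 | groups scoring 0 on both growth and production objectives excluded |

Gene-association canonicalization is purely textual (lowercase, sort the
operands of the commutative `and`/`or`, flatten associative repeats,
keep nesting across operators).  No boolean minimization: an isozyme
pair `a or b` is a different enzyme than `a` alone, matching how
reconstructions assign reactions.

## Selecting targets: bilevel MILP

Given an incumbent design, the next design is the solution of

    outer:  maximize v_export over selections y within Hamming
            distance k of the incumbent (additions and removals count),
            one sign per group
    inner:  v must be optimal for the Z_system induced by y

Inner optimality is encoded by LP strong duality.  Because `Z_system` is
linear in `y`, dual feasibility needs no linearization; only the
strong-duality row contains `y*v` products, replaced by inclusion
variables `w` with a big-M linearization (`M_j = 1.05 * max(|lb_j|,
|ub_j|)`).  The strong-duality equality is enforced as an absolute band
of +-1e-6: the band must sit well below the smallest objective margin
that distinguishes designs (set by `delta_progress`, see below), so it
is deliberately *not* scaled by the big-M magnitudes.  Dual variables
are boxed at 1e4 x the objective-coefficient scale purely for solver
stability.  The MILP is solved by HiGHS (via `scipy.optimize.milp`,
single-threaded, `mip_rel_gap=0`); if HiGHS reports a solve error the
problem is re-issued once with the presolve setting flipped, which in
practice resolves its occasional difficulty with the narrow duality band.

Degenerate inner optima are resolved *optimistically*: a design's
reported production is the maximum export flux among inner-optimal
states (a secondary LP anchored at the system-objective optimum within
1e-9).  The optimistic convention is applied identically in the MILP
(whose outer objective is export), in `evaluate_design`, and in the
brute-force oracle, so all three report the same number.  If the MILP's
design does not strictly improve on the incumbent's production, the
incumbent is returned unchanged — the neighborhood is exhausted.

The testing oracle (`brute_force_design_search`) enumerates every
selection set within distance k, evaluates each by single-level FBA, and
is exact by construction; it refuses libraries above 24 entries.  Ties
are compared at 1e-9 production resolution and broken toward smaller
designs, then lexicographically.

## Progressive target discovery

Once a design reaches maximal production, no further targets are needed
— unless growth is made harder to ignore.  After each successful
iteration the growth weight is escalated to

    gamma_new = sum_included beta_jl * (v_j - v_j^maxgrowth) / g_max
                + delta_progress

where `v^maxgrowth` is the flux state at the pure growth optimum and
`g_max` the maximal biomass flux.  The division by `g_max` expresses the
redirection strength per unit of attainable growth objective; for
genome-scale reconstructions with biomass flux near 1 it is a no-op, and
on the toy fixtures (where maximal growth equals the uptake bound) it is
what makes the escalation recruit exactly one additional chain enzyme
per iteration rather than overshooting past the entire library.  This
was the one genuinely open normalization choice in the procedure;
`update_progressive_growth` defaults to `biomass_scale=1.0` (the raw
objective scale) and the search driver passes `g_max`.

`delta_progress` (default 1e-4) only guarantees strictness of the
escalation.  Final designs and fluxes are invariant as it sweeps
1e-6..1e-2; below ~1e-7 it would approach the MILP's duality band and
solver noise, which is why the default sits two orders above.

The loop's control rule, on (production fraction, new targets found):

* below threshold, new targets -> continue at the same gamma;
* at/above threshold, no new targets -> escalate gamma;
* at/above threshold, new targets -> checkpoint the design, escalate;
* below threshold, no new targets -> terminate.

The production fraction is measured against the FBA maximum of the
export flux (under the biomass floor when configured); the threshold is
inclusive at its default 0.8.  The final design is the checkpoint with
the highest gamma.  An optional biomass floor (fraction of maximal
growth, default off for toys, conventionally 0.2 for genome-scale runs)
is imposed as a lower bound on the biomass flux in every evaluation.

## Dependency network mapping

Pooled targets from separate searches are recombined: every subset up to
size N is evaluated by single-level FBA at a fixed weak `gamma = 0.02`
(no escalation here — the point is the minimal core, not the largest
design).  A subset qualifies when production reaches 20% of the maximum
possible and strictly exceeds (by 1e-6 absolute) every proper subset,
including the empty-design baseline.  Singletons and pairs become an
undirected graph; edges at >= 90% of maximal production are flagged.
Subsets are enumerated in lexicographic order over a deduplicated,
canonically sorted pool, so output is invariant to pool ordering.

## Linear-programming layer

All LPs run on HiGHS through `scipy.optimize.linprog`: deterministic,
single-threaded, duals exposed.  Feasibility/optimality tolerances are
1e-9 on the toy scale; genome-scale models should use ~1e-6 and may
apply the optional global flux rescaling (`MetabolicNetwork.
scale_fluxes`) to improve conditioning.  Sensitivity scores are reduced
costs read from the one dual vertex the solver returns (`score_j = c_j +
u.S_j`, zero for basic reactions, zero by contract for reactions with
`lb == ub`).  Dual degeneracy — a variable at a bound with zero reduced
cost — is flagged on the result.  The finite-difference mode re-solves
with the flux pinned at `v* +- 1e-3`: central where both probes are
feasible; one-sided when the reaction's own bound blocks a probe (that
slope *is* the reduced cost of a nonbasic variable); zero when the rest
of the network blocks a probe, because the two-sided marginal does not
exist there.  Under this convention the two modes agree to 1e-6 on
nondegenerate fixtures; under degeneracy the dual mode reports one valid
subgradient and the flag warns the caller.

## Toy fixtures and what they do (not) show

The generator builds four deterministic topologies with uptake bound 10
(so maximal growth = maximal export = 10, biomass drawing substrate 1:1):

* **branch** — substrate splits between biomass and a 2-step export
  branch: the elementary growth/production trade-off;
* **linear_chain** (length parameter) — the product hangs at the end of
  a chain of distinctly catalyzed steps off the growth precursor; the
  coefficient needed to win the substrate grows with gamma, so chain
  enzymes must be recruited in concert — the behavior bound-based
  encodings cannot express;
* **dead_end** — branch plus a zero-capacity reaction, exercising
  sensitivity-library exclusion;
* **drain_competition** — growth is routed *through* the drain enzyme's
  product (uptake -> A; A -> X; X -> biomass; A -> C via enzB; the drain
  C -> X via enzD; C -> P -> export uncatalyzed).  Up-regulating enzB
  alone feeds the drain; down-regulating enzD alone leaves growth the
  only incentive.  Exactly the pair {enzB up, enzD down} yields full
  production, giving dependency mapping a known minimal pair.  Routing
  growth through the drain is deliberate: under the optimistic
  tie-break a merely *parallel* drain is objective-neutral once its
  competitor is incentivized, and either singleton would spuriously
  reach full production.

Internal reaction caps are 50 (loose, since mass balance limits all
fluxes to the uptake bound); tight caps keep the MILP's big-M small.

These fixtures are small, fully coupled, and degenerate in ways
genome-scale models are not: they have no cofactors, no alternate
routes, no excess capacity.  Passing tests on them demonstrates the
*algorithms* — exactness of the bilevel encoding against enumeration,
the escalation dynamics, the dependency logic — not predictive accuracy
on real metabolism.  One consequence is worth naming: anchored
flux-variability ranges on the branch toy are disjoint for anchor
fractions above 0.5 (the toy has zero slack), so the "boundary analysis
finds no targets at 80% anchoring" contrast that holds on slack-rich
genome-scale networks appears on the toy only at fractions <= 0.5.

## Problem sizes and numerical defaults

| quantity | default | why |
|---|---|---|
| feas/opt tolerance (toy) | 1e-9 | clean rational data |
| strong-duality band | 1e-6 absolute | below delta_progress margins, above solver noise |
| big-M safety factor | 1.05 | bounds are exact; margin for roundoff |
| tie-break anchor | 1e-9 | optimistic production read-off |
| gamma initial | 0.02 | weak growth, the dependency-mapping convention |
| delta_progress | 1e-4 | two orders above the duality band |
| production threshold | 0.8 (inclusive) | checkpointing rule |
| oracle enumeration cap | 24 entries | < 1e6 LPs at k <= 3 |
| MILP time limit | 3600 s per iteration | returns best feasible on timeout |

The oracle-agreement battery in the test suite covers 144 combinations
(9 topologies x 2 libraries where the enumeration cap permits x k in
{1,2,3} x gamma in {0.02, 0.5, 2.5}) and runs in under two minutes on
one CPU; the acceptance script uses a 56-combination battery with
seed-jittered uptake bounds.

## Known limitations

* Big-M strong duality is the only inner-optimality encoding; no
  indicator constraints or KKT complementarity.  Very wide flux bounds
  weaken the linearization — rescale fluxes first.
* The optimistic tie-break is a convention; a pessimistic cell could
  realize less production than reported for weakly incentivized designs.
* Sensitivity scores under dual degeneracy depend on the returned dual
  vertex (flagged, not resolved).
* The search is a local neighborhood method; nothing certifies global
  optimality across iterations, only within each k-neighborhood.
* No thermodynamic, regulatory, or compartment mass/charge checks.
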