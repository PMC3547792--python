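"""In-memory representation of a stoichiometric metabolic network.

The network is a plain container: an ordered reaction list ``J``, a sparse
stoichiometric matrix ``S`` (metabolites x reactions), per-reaction flux
bounds in umol/gDW/h, per-reaction gene-association strings, and the id of
the biomass pseudo-reaction.  All analysis modules consume this container;
file formats are handled in :mod:`fluxredirect.model_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


class NetworkError(ValueError):
    """Raised for inconsistent or invalid network definitions."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric model with bounds and gene associations.

    Parameters
    ----------
    metabolites:
        Ordered metabolite ids (rows of ``S``).
    reactions:
        Ordered reaction ids ``J`` (columns of ``S``); order is meaningful
        and preserved by all I/O round trips.
    stoichiometry:
        ``{reaction_id: {metabolite_id: coefficient}}``; negative
        coefficients consume, positive produce.
    lower_bound, upper_bound:
        Per-reaction flux bounds (umol/gDW/h).  Reversible reactions are
        kept as signed fluxes; they are never split into two columns.
    gene_association:
        Per-reaction boolean gene-association string (may be ``""`` for
        spontaneous, exchange and pseudo reactions).
    biomass_reaction:
        Id of the biomass pseudo-reaction (the growth objective).
    """

    metabolites: list[str]
    reactions: list[str]
    stoichiometry: dict[str, dict[str, float]]
    lower_bound: dict[str, float]
    upper_bound: dict[str, float]
    gene_association: dict[str, str] = field(default_factory=dict)
    biomass_reaction: str = ""
    name: str = "network"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        met_set = set(self.metabolites)
        rxn_set = set(self.reactions)
        if len(met_set) != len(self.metabolites):
            raise NetworkError("duplicate metabolite ids")
        if len(rxn_set) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")
        for rxn, col in self.stoichiometry.items():
            if rxn not in rxn_set:
                raise NetworkError(f"stoichiometry references undeclared reaction {rxn!r}")
            for met in col:
                if met not in met_set:
                    raise NetworkError(
                        f"reaction {rxn!r} references undeclared metabolite {met!r}"
                    )
        for rxn in self.reactions:
            lb = self.lower_bound.get(rxn)
            ub = self.upper_bound.get(rxn)
            if lb is None or ub is None:
                raise NetworkError(f"missing bounds for reaction {rxn!r}")
            if lb > ub:
                raise NetworkError(f"lower bound exceeds upper bound for {rxn!r}")
        if self.biomass_reaction and self.biomass_reaction not in rxn_set:
            raise NetworkError(
                f"biomass reaction {self.biomass_reaction!r} not in reaction list"
            )

    # -- derived views ------------------------------------------------
    @property
    def exchange_reactions(self) -> list[str]:
        """Reactions that create or destroy mass (one-sided stoichiometry).

        A reaction whose nonzero coefficients are all negative (pure drain)
        or all positive (pure source), including empty columns, crosses the
        system boundary.  The biomass pseudo-reaction is excluded.
        """
        out = []
        for rxn in self.reactions:
            if rxn == self.biomass_reaction:
                continue
            coefs = [c for c in self.stoichiometry.get(rxn, {}).values() if c != 0.0]
            if not coefs or all(c < 0 for c in coefs) or all(c > 0 for c in coefs):
                out.append(rxn)
        return out

    def smatrix(self) -> sparse.csr_matrix:
        """Sparse stoichiometric matrix (metabolites x reactions)."""
        mi = {m: i for i, m in enumerate(self.metabolites)}
        ri = {r: j for j, r in enumerate(self.reactions)}
        rows, cols, vals = [], [], []
        for rxn, col in self.stoichiometry.items():
            j = ri[rxn]
            for met, coef in col.items():
                if coef != 0.0:
                    rows.append(mi[met])
                    cols.append(j)
                    vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([self.lower_bound[r] for r in self.reactions], dtype=float)
        ub = np.array([self.upper_bound[r] for r in self.reactions], dtype=float)
        return lb, ub

    def reaction_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.reactions)}

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            stoichiometry={r: dict(c) for r, c in self.stoichiometry.items()},
            lower_bound=dict(self.lower_bound),
            upper_bound=dict(self.upper_bound),
            gene_association=dict(self.gene_association),
            biomass_reaction=self.biomass_reaction,
            name=self.name,
        )

    def scale_fluxes(self, factor: float) -> "MetabolicNetwork":
        """Return a copy with all flux bounds multiplied by ``factor``.

        Genome-scale runs sometimes shrink the flux scale (e.g. by 10x) to
        improve MILP conditioning; stoichiometry is unchanged.
        """
        out = self.copy()
        for r in out.reactions:
            out.lower_bound[r] *= factor
            out.upper_bound[r] *= factor
        return out


@dataclass
class ProductDefinition:
    """A metabolite to overproduce, exported by a dedicated drain reaction.

    ``recycled_metabolites`` maps metabolite ids to the stoichiometric
    coefficient returned to the network per unit of export, e.g. freeing
    the CoA moiety when an acyl-CoA leaves the system.
    """

    product_metabolite: str
    export_reaction_id: str
    recycled_metabolites: dict[str, float] = field(default_factory=dict)


def add_product_export(
    network: MetabolicNetwork, product: ProductDefinition, max_export: float = 1000.0
) -> MetabolicNetwork:
    """Return a copy of ``network`` with the product-export reaction added.

    The new reaction irreversibly consumes one unit of the product
    metabolite per unit flux and returns each recycled metabolite at its
    stated coefficient.  It carries no gene association and is therefore
    never an engineering target.  Existing reactions are untouched.
    """
    if product.export_reaction_id in set(network.reactions):
        raise NetworkError(
            f"export reaction id {product.export_reaction_id!r} already present"
        )
    met_set = set(network.metabolites)
    if product.product_metabolite not in met_set:
        raise NetworkError(
            f"product metabolite {product.product_metabolite!r} not in network"
        )
    for met in product.recycled_metabolites:
        if met not in met_set:
            raise NetworkError(f"recycled metabolite {met!r} not in network")
    out = network.copy()
    rid = product.export_reaction_id
    col: dict[str, float] = {product.product_metabolite: -1.0}
    for met, coef in product.recycled_metabolites.items():
        col[met] = col.get(met, 0.0) + float(coef)
    out.reactions.append(rid)
    out.stoichiometry[rid] = col
    out.lower_bound[rid] = 0.0
    out.upper_bound[rid] = float(max_export)
    out.gene_association[rid] = ""
    out.validate()
    return out
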