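"""Model input/output: SBML (via COBRApy) and a simple tabular dialect.

The tabular dialect is a directory of tab-separated files::

    metabolites.tsv   id <tab> name <tab> compartment
    reactions.tsv     id <tab> equation <tab> lb <tab> ub <tab> gene_association
    model.tsv         key <tab> value   (name, biomass_reaction)

Reaction equations use ``->`` (irreversible as written) or ``<->``
(reversible) with ``+``-separated, optionally coefficient-prefixed terms,
e.g. ``glc + 2 atp -> 2 g3p``.  An empty side denotes a boundary
(exchange) reaction.  Reaction order is file order and is preserved on
write, so load -> write -> load round-trips bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

from .network import MetabolicNetwork, ProductDefinition


class FormatError(ValueError):
    """Malformed model file; the message names the first offending record."""


class ConfigurationError(ValueError):
    """Structurally valid input missing required configuration (e.g. biomass)."""


# ---------------------------------------------------------------- tabular

def _parse_side(text: str, rxn_id: str) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in text.split("+"):
        parts = term.split()
        if not parts:
            raise FormatError(f"reaction {rxn_id!r}: empty term in equation")
        if len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError as exc:
                raise FormatError(
                    f"reaction {rxn_id!r}: bad coefficient {parts[0]!r}"
                ) from exc
            met = parts[1]
        elif len(parts) == 1:
            coef, met = 1.0, parts[0]
        else:
            raise FormatError(f"reaction {rxn_id!r}: cannot parse term {term.strip()!r}")
        out[met] = out.get(met, 0.0) + coef
    return out


def _parse_equation(eq: str, rxn_id: str) -> dict[str, float]:
    for arrow in ("<->", "->"):
        if arrow in eq:
            left, right = eq.split(arrow, 1)
            stoich: dict[str, float] = {}
            for met, coef in _parse_side(left, rxn_id).items():
                stoich[met] = stoich.get(met, 0.0) - coef
            for met, coef in _parse_side(right, rxn_id).items():
                stoich[met] = stoich.get(met, 0.0) + coef
            return stoich
    raise FormatError(f"reaction {rxn_id!r}: equation lacks '->' or '<->'")


def _format_side(items: list[tuple[str, float]]) -> str:
    parts = []
    for met, coef in items:
        parts.append(met if coef == 1.0 else f"{coef:.10g} {met}")
    return " + ".join(parts)


def _format_equation(stoich: dict[str, float], reversible: bool) -> str:
    left = [(m, -c) for m, c in stoich.items() if c < 0]
    right = [(m, c) for m, c in stoich.items() if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{_format_side(sorted(left))} {arrow} {_format_side(sorted(right))}".strip()


def _read_tsv(path: Path, n_cols: int, what: str):
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < n_cols:
                cells += [""] * (n_cols - len(cells))
            rows.append(cells[:n_cols])
    del header
    if not rows:
        raise FormatError(f"{what} file {path} has no records")
    return rows


def load_tabular(path) -> MetabolicNetwork:
    path = Path(path)
    met_rows = _read_tsv(path / "metabolites.tsv", 3, "metabolite")
    rxn_rows = _read_tsv(path / "reactions.tsv", 5, "reaction")
    meta = {}
    model_file = path / "model.tsv"
    if model_file.exists():
        with open(model_file) as fh:
            fh.readline()
            for line in fh:
                if line.strip():
                    key, _, value = line.rstrip("\n").partition("\t")
                    meta[key] = value
    metabolites = [r[0] for r in met_rows]
    reactions, stoich, lbs, ubs, gpr = [], {}, {}, {}, {}
    for rid, equation, lb, ub, assoc in rxn_rows:
        if rid in stoich:
            raise FormatError(f"duplicate reaction id {rid!r}")
        reactions.append(rid)
        stoich[rid] = _parse_equation(equation, rid)
        try:
            lbs[rid], ubs[rid] = float(lb), float(ub)
        except ValueError as exc:
            raise FormatError(f"reaction {rid!r}: bad bounds {lb!r}/{ub!r}") from exc
        gpr[rid] = assoc
    biomass = meta.get("biomass_reaction", "")
    if not biomass:
        raise ConfigurationError(f"model at {path} declares no biomass_reaction")
    if biomass not in stoich:
        raise ConfigurationError(f"biomass reaction {biomass!r} not among reactions")
    return MetabolicNetwork(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=stoich,
        lower_bound=lbs,
        upper_bound=ubs,
        gene_association=gpr,
        biomass_reaction=biomass,
        name=meta.get("name", path.name),
    )


def write_tabular(network: MetabolicNetwork, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tcompartment\n")
        for met in network.metabolites:
            fh.write(f"{met}\t{met}\tc\n")
    with open(path / "reactions.tsv", "w") as fh:
        fh.write("id\tequation\tlb\tub\tgene_association\n")
        for rid in network.reactions:
            lb, ub = network.lower_bound[rid], network.upper_bound[rid]
            eq = _format_equation(network.stoichiometry.get(rid, {}), lb < 0)
            fh.write(
                f"{rid}\t{eq}\t{lb:.10g}\t{ub:.10g}\t{network.gene_association.get(rid, '')}\n"
            )
    with open(path / "model.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"name\t{network.name}\n")
        fh.write(f"biomass_reaction\t{network.biomass_reaction}\n")


# ------------------------------------------------------------------ SBML

def load_sbml(path, biomass_reaction: str | None = None) -> MetabolicNetwork:
    """Read an SBML (L3 + FBC) model through COBRApy.

    The biomass reaction is taken from the model's FBC objective unless
    given explicitly; a model without either raises
    :class:`ConfigurationError`.
    """
    import cobra.io

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a mixed bag of exception types
        raise FormatError(f"cannot parse SBML file {path}: {exc}") from exc
    reactions, stoich, lbs, ubs, gpr = [], {}, {}, {}, {}
    for rxn in model.reactions:
        reactions.append(rxn.id)
        stoich[rxn.id] = {met.id: float(coef) for met, coef in rxn.metabolites.items()}
        lbs[rxn.id], ubs[rxn.id] = float(rxn.lower_bound), float(rxn.upper_bound)
        gpr[rxn.id] = rxn.gene_reaction_rule or ""
    if biomass_reaction is None:
        objective = [r.id for r in model.reactions if r.objective_coefficient]
        if len(objective) != 1:
            raise ConfigurationError(
                f"SBML model {path} has no single objective reaction; "
                "pass biomass_reaction explicitly"
            )
        biomass_reaction = objective[0]
    return MetabolicNetwork(
        metabolites=[m.id for m in model.metabolites],
        reactions=reactions,
        stoichiometry=stoich,
        lower_bound=lbs,
        upper_bound=ubs,
        gene_association=gpr,
        biomass_reaction=biomass_reaction,
        name=model.id or Path(str(path)).stem,
    )


def write_sbml(network: MetabolicNetwork, path) -> None:
    import cobra
    import cobra.io

    model = cobra.Model(network.name)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in network.metabolites}
    for rid in network.reactions:
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = network.lower_bound[rid]
        rxn.upper_bound = network.upper_bound[rid]
        model.add_reactions([rxn])
        rxn.add_metabolites(
            {mets[m]: c for m, c in network.stoichiometry.get(rid, {}).items()}
        )
        assoc = network.gene_association.get(rid, "")
        if assoc:
            rxn.gene_reaction_rule = assoc
    if network.biomass_reaction:
        model.objective = network.biomass_reaction
    cobra.io.write_sbml_model(model, str(path))


# ------------------------------------------------------------- dispatch

def load_model(path, dialect: str = "auto",
               biomass_reaction: str | None = None) -> MetabolicNetwork:
    """Load a model in the named dialect (``sbml`` | ``tabular`` | ``auto``)."""
    path = Path(path)
    if dialect == "auto":
        dialect = "tabular" if path.is_dir() else "sbml"
    if dialect == "tabular":
        network = load_tabular(path)
        if biomass_reaction:
            network.biomass_reaction = biomass_reaction
            network.validate()
        return network
    if dialect == "sbml":
        return load_sbml(path, biomass_reaction)
    raise ValueError(f"unknown model dialect {dialect!r}")


def write_model(network: MetabolicNetwork, path, dialect: str = "tabular") -> None:
    if dialect == "tabular":
        write_tabular(network, path)
    elif dialect == "sbml":
        write_sbml(network, path)
    else:
        raise ValueError(f"unknown model dialect {dialect!r}")


# ------------------------------------------------- product definitions

def load_product_definition(source) -> ProductDefinition:
    """Product definition from a YAML/JSON file path or a mapping.

    Keys: ``product`` (metabolite id), ``export_id`` (new reaction id),
    optional ``recycle`` (metabolite -> coefficient map).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
    else:
        data = dict(source)
    try:
        return ProductDefinition(
            product_metabolite=data["product"],
            export_reaction_id=data["export_id"],
            recycled_metabolites={
                str(k): float(v) for k, v in (data.get("recycle") or {}).items()
            },
        )
    except KeyError as exc:
        raise ConfigurationError(f"product definition missing key {exc}") from exc
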