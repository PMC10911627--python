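"""Stoichiometric model data structures, SBML I/O, and editing operations.

The central object is :class:`MetabolicModel`: metabolites with compartments,
bounded reactions with gene-protein-reaction (GPR) rules, and an objective
reaction (typically biomass). Editing operations (knockouts, media, pathway
additions) are pure functions returning modified copies, so a wild-type model
can be reused across many strain-design simulations.

SBML reading and writing is delegated to cobrapy/libsbml (fbc-v2 emitted,
legacy bounds accepted on read); everything else in this package operates on
the plain data structures defined here.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import EMPTY_GPR, GPR

DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """A model violates a structural invariant (dangling ids, bad bounds...)."""


class SBMLReadError(ValueError):
    """The SBML document could not be parsed into a valid model."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """A bounded reaction; negative stoichiometric coefficients are consumed.

    Bounds are in mmol gDW^-1 h^-1 (the biomass pseudo-reaction carries h^-1).
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = EMPTY_GPR
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.id
        if isinstance(self.gpr, str):
            self.gpr = GPR.from_string(self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MediumSpec:
    """Maximum uptake rates per exchange reaction (positive magnitudes).

    Exchanges absent from ``uptake_limits`` are closed for uptake; secretion
    bounds are never touched. Uptake is represented as negative exchange flux.
    """

    uptake_limits: dict[str, float] = field(default_factory=dict)
    name: str = "medium"

    def __post_init__(self) -> None:
        for rxn_id, limit in self.uptake_limits.items():
            if limit < 0:
                raise ValueError(
                    f"uptake limit for {rxn_id} must be non-negative, got {limit}"
                )


class MetabolicModel:
    """A stoichiometric network with GPRs, bounds, and an objective reaction."""

    def __init__(
        self,
        model_id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_reaction: str | None = None,
        peripheral_reactions: Iterable[str] = (),
    ) -> None:
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_reaction = objective_reaction
        # reactions declared hard to engineer (excluded from knockout candidates)
        self.peripheral_reactions: set[str] = set(peripheral_reactions)
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)

    # -- construction -------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, allow_new_metabolites: bool = False) -> None:
        if rxn.id in self.reactions:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                if allow_new_metabolites:
                    comp = met_id.rsplit("_", 1)[-1] if "_" in met_id else "c"
                    self.add_metabolite(Metabolite(met_id, compartment=comp))
                else:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                    )
        self.reactions[rxn.id] = rxn

    # -- views ---------------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.gpr.genes()
        return frozenset(out)

    @property
    def compartments(self) -> frozenset[str]:
        return frozenset(m.compartment for m in self.metabolites.values())

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """Sparse S (metabolites x reactions) plus row/column id orderings."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(coef)
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    # -- reaction categories -------------------------------------------------
    def is_boundary(self, rxn_id: str) -> bool:
        """Exchange/sink/demand: all metabolites on one side of the arrow."""
        stoich = self.reactions[rxn_id].stoichiometry
        if not stoich:
            return True
        signs = {np.sign(c) for c in stoich.values() if c != 0}
        return len(signs) <= 1

    def is_exchange(self, rxn_id: str) -> bool:
        """Boundary reaction on extracellular metabolites only."""
        stoich = self.reactions[rxn_id].stoichiometry
        return self.is_boundary(rxn_id) and all(
            self.metabolites[m].compartment == "e" for m in stoich
        )

    def is_transport(self, rxn_id: str) -> bool:
        comps = {
            self.metabolites[m].compartment
            for m in self.reactions[rxn_id].stoichiometry
        }
        return len(comps) >= 2

    def exchange_ids(self) -> list[str]:
        return [r for r in self.reactions if self.is_exchange(r)]

    # -- invariants ----------------------------------------------------------
    def validate(self) -> None:
        for rid, rxn in self.reactions.items():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rid!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            if not rxn.stoichiometry and not self.is_boundary(rid):
                raise ModelValidationError(f"reaction {rid!r} has empty stoichiometry")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rid!r} references undeclared metabolite {met_id!r}"
                    )
        if self.objective_reaction is not None and (
            self.objective_reaction not in self.reactions
        ):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    # -- copies and equality -------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def content_key(self):
        """Hashable snapshot of model content; used to assert purity of edits."""
        return (
            self.id,
            tuple(sorted((m.id, m.name, m.compartment, m.formula) for m in self.metabolites.values())),
            tuple(
                sorted(
                    (
                        r.id,
                        tuple(sorted(r.stoichiometry.items())),
                        r.lower_bound,
                        r.upper_bound,
                        r.gpr.to_string(),
                    )
                    for r in self.reactions.values()
                )
            ),
            self.objective_reaction,
        )

    def equivalent(self, other: "MetabolicModel") -> bool:
        """Structural equality up to element ordering (ids, stoichiometry, bounds, GPR)."""
        return self.content_key() == other.content_key()


# ---------------------------------------------------------------------------
# SBML I/O (via cobrapy / libsbml; fbc-v2 on write)
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment, formula=m.formula
        )
        for m in model.metabolites.values()
    }
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id, name=rxn.name)
        cr.add_metabolites({mets[mid]: coef for mid, coef in rxn.stoichiometry.items()})
        cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():  # GPRs after reactions are registered
        if not rxn.gpr.is_empty:
            cm.reactions.get_by_id(rxn.id).gene_reaction_rule = rxn.gpr.to_string()
    if model.objective_reaction is not None:
        cm.objective = model.objective_reaction
    return cm


def _from_cobra(cm, model_id: str | None = None) -> MetabolicModel:
    model = MetabolicModel(model_id or cm.id or "model")
    for met in cm.metabolites:
        model.add_metabolite(
            Metabolite(
                met.id,
                name=met.name or met.id,
                compartment=met.compartment or "c",
                formula=met.formula or None,
            )
        )
    objective_ids = [
        r.id for r in cm.reactions if getattr(r, "objective_coefficient", 0.0)
    ]
    for rxn in cm.reactions:
        if rxn.lower_bound is None or rxn.upper_bound is None:
            raise SBMLReadError(f"reaction {rxn.id!r} is missing flux bounds")
        model.add_reaction(
            Reaction(
                rxn.id,
                stoichiometry={m.id: c for m, c in rxn.metabolites.items()},
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=GPR.from_string(rxn.gene_reaction_rule or ""),
                name=rxn.name or rxn.id,
            )
        )
    if objective_ids:
        model.objective_reaction = objective_ids[0]
    model.validate()
    return model


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML file (fbc-v2 or legacy kinetic-law bounds) into a model."""
    import cobra

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various parse errors
        raise SBMLReadError(f"could not parse SBML file {path}: {exc}") from exc
    return _from_cobra(cm)


def write_sbml(model: MetabolicModel, path: str | Path) -> Path:
    """Write the model as SBML level 3 with fbc-v2 flux bounds and GPRs."""
    import cobra

    model.validate()
    path = Path(path)
    cm = _to_cobra(model)
    cobra.io.write_sbml_model(cm, str(path))
    return path


# ---------------------------------------------------------------------------
# GPR evaluation and knockout operations
# ---------------------------------------------------------------------------

def evaluate_gpr(rule: GPR | str, knocked: Iterable[str] = ()) -> bool:
    """True iff the reaction's enzyme remains functional under gene knockouts."""
    if isinstance(rule, str):
        rule = GPR.from_string(rule)
    return rule.evaluate(knocked)


def apply_gene_knockouts(
    model: MetabolicModel, genes: Iterable[str]
) -> MetabolicModel:
    """Zero the bounds of every reaction whose GPR evaluates false.

    Pure: the input model is untouched. Reactions without gene association are
    never affected.
    """
    genes = set(genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene ids: {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions.values():
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def apply_reaction_knockouts(
    model: MetabolicModel, reactions: Iterable[str]
) -> MetabolicModel:
    """Disable the named reactions in both directions (pure function)."""
    reactions = set(reactions)
    unknown = reactions - set(model.reactions)
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
    out = model.copy()
    for rid in reactions:
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
    return out


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Open listed exchanges for uptake at the given rates; close the rest.

    Uptake is negative exchange flux, so a limit of 30 sets lower_bound = -30.
    Secretion (upper) bounds are untouched.
    """
    exchanges = set(model.exchange_ids())
    bad = set(medium.uptake_limits) - exchanges
    if bad:
        raise KeyError(
            f"medium keys are not exchange reactions in the model: {sorted(bad)}"
        )
    out = model.copy()
    for rid in exchanges:
        rxn = out.reactions[rid]
        if rid in medium.uptake_limits:
            rxn.lower_bound = -float(medium.uptake_limits[rid])
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out


# ---------------------------------------------------------------------------
# Reaction-table format and pathway additions
# ---------------------------------------------------------------------------

def parse_equation(equation: str) -> dict[str, float]:
    """Parse ``"mr[c] + 2.0 nadh[c] --> anth[c]"`` into a stoichiometry map.

    Metabolite tokens are ``base[compartment]`` and are mapped onto ids
    ``base_compartment``. ``-->`` is irreversible as written, ``<=>`` marks a
    reversible equation (the caller's bounds decide), ``<--`` flips the sides.
    An empty side denotes a boundary reaction.
    """
    for arrow in ("<=>", "-->", "<--", "->", "<->"):
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            flip = arrow == "<--"
            break
    else:
        raise ValueError(f"no reaction arrow found in equation {equation!r}")
    if flip:
        left, right = right, left

    def parse_side(side: str, sign: float, stoich: dict[str, float]) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ValueError(f"empty term in equation {equation!r}")
            parts = term.split()
            if len(parts) == 2:
                coef = float(parts[0])
                token = parts[1]
            elif len(parts) == 1:
                coef, token = 1.0, parts[0]
            else:
                raise ValueError(f"cannot parse term {term!r} in {equation!r}")
            if not (token.endswith("]") and "[" in token):
                raise ValueError(
                    f"metabolite token {token!r} lacks a [compartment] suffix"
                )
            base, comp = token[:-1].split("[", 1)
            met_id = f"{base}_{comp}"
            stoich[met_id] = stoich.get(met_id, 0.0) + sign * coef

    stoich: dict[str, float] = {}
    parse_side(left, -1.0, stoich)
    parse_side(right, +1.0, stoich)
    return {m: c for m, c in stoich.items() if c != 0.0}


def equation_is_reversible(equation: str) -> bool:
    return "<=>" in equation or "<->" in equation


def read_reaction_table(path: str | Path) -> list[Reaction]:
    """Read the tab-separated pathway format: id, equation, lb, ub, gpr.

    Lines starting with ``#`` and blank lines are skipped; the gpr column may
    be empty. Bounds columns may be empty, defaulting to the equation arrow
    (irreversible: 0..1000; reversible: -1000..1000).
    """
    path = Path(path)
    reactions = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least id and equation")
        rid, equation = fields[0].strip(), fields[1].strip()
        lb_s = fields[2].strip() if len(fields) > 2 else ""
        ub_s = fields[3].strip() if len(fields) > 3 else ""
        gpr_s = fields[4].strip() if len(fields) > 4 else ""
        rev = equation_is_reversible(equation)
        lb = float(lb_s) if lb_s else (-DEFAULT_BOUND if rev else 0.0)
        ub = float(ub_s) if ub_s else DEFAULT_BOUND
        reactions.append(
            Reaction(
                rid,
                stoichiometry=parse_equation(equation),
                lower_bound=lb,
                upper_bound=ub,
                gpr=GPR.from_string(gpr_s),
            )
        )
    return reactions


def add_reactions(
    model: MetabolicModel,
    reactions: Iterable[Reaction],
    on_duplicate: str = "error",
) -> MetabolicModel:
    """Return a copy of the model with the reactions added.

    New metabolites referenced by the additions are created with compartments
    parsed from their id suffix. ``on_duplicate``: ``"error"`` (default) raises
    on an already-present reaction id; ``"skip"`` leaves the existing reaction
    in place. Silent duplication is never allowed — it would corrupt S.
    """
    if on_duplicate not in ("error", "skip"):
        raise ValueError("on_duplicate must be 'error' or 'skip'")
    out = model.copy()
    for rxn in reactions:
        if rxn.id in out.reactions:
            if on_duplicate == "error":
                raise ModelValidationError(
                    f"reaction {rxn.id!r} already present in model {model.id!r}"
                )
            continue
        out.add_reaction(copy.deepcopy(rxn), allow_new_metabolites=True)
    return out


def _bundled(name: str) -> Path:
    return Path(importlib.resources.files("azodesign.data") / name)


def mr_transport_reactions() -> list[Reaction]:
    """The methyl-red uptake block: azoreductase plus MR transport/exchange.

    AzoR_MR consumes exactly 2 NADH per methyl red, splitting the azo bond
    into N,N-dimethyl-4-phenylenediamine and anthranilate.
    """
    return read_reaction_table(_bundled("mr_transport.tsv"))


def act_pathway_reactions() -> list[Reaction]:
    """Anthranilate dioxygenase plus a lumped actinorhodin biosynthesis block.

    This is a synthetic stand-in for the full heterologous pathway (the exact
    per-step stoichiometries live in the supplementary material of the source
    model and are not bundled); it preserves the features the analysis needs:
    catechol formation from anthranilate (NADH-consuming), acetyl-CoA /
    malonyl-CoA consumption, and net NADH regeneration by ACT synthesis.
    """
    return read_reaction_table(_bundled("act_pathway_synthetic.tsv"))


def apply_dye_pathway_extension(
    model: MetabolicModel, on_duplicate: str = "error"
) -> MetabolicModel:
    """Add the MR-to-ACT conversion pathway to a base model.

    Mirrors the published model-editing sequence: first the azoreductase and
    MR transport/exchange block, then the ACT pathway (anthranilate
    dioxygenase + lumped polyketide synthesis). Requires the base model to
    supply the precursor metabolites (acetyl-CoA, NADH/NAD, oxygen...).
    """
    out = add_reactions(model, mr_transport_reactions(), on_duplicate=on_duplicate)
    out = add_reactions(out, act_pathway_reactions(), on_duplicate=on_duplicate)
    missing = [
        m
        for m in ("accoa_c", "nadh_c", "nad_c", "o2_c")
        if m not in model.metabolites
    ]
    if missing:
        raise ModelValidationError(
            f"base model lacks precursor metabolites required by the pathway: {missing}"
        )
    return out
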