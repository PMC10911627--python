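"""Synthetic fixture models with certified analytic optima.

Two families are generated here, both small enough that every downstream
stage (FBA/FVA, envelopes, flux-sums, gap filling, cut-set enumeration) can
be exercised without any external model file:

* **Toy coupling models** (:func:`make_toy_model`): an abstract 12-25 reaction
  network with a substrate entry, a central carbon node, a redox-cofactor
  (NADH) cycle closed by respiration and ATP maintenance, a biomass reaction,
  and a product pathway that regenerates NADH. In *aromatic* mode the
  substrate's catabolism consumes NADH (like azo-dye reduction), and knocking
  out the planted set of alternative NADH sources growth-couples the product.
  In *sugar* mode catabolism produces NADH (like glycolysis) and no coupling
  cut set exists. Both facts, and the biomass/product optima, are certified
  at generation time: optima by closed-form rational arithmetic plus an LP
  cross-check, with an exactly mass-balanced rational flux vector stored in
  the metadata, and the coupling dichotomy by the exhaustive cut-set oracle.

* **A demo central-carbon model** (:func:`make_demo_model`): a named-metabolite
  mini-network (glucose entry, lumped glycolysis/TCA/oxidative
  phosphorylation, catechol meta-cleavage) onto which the bundled methyl-red
  and actinorhodin pathway blocks can be grafted, emulating the structure of
  the engineered production host at a size where results remain auditable.

All stoichiometry is integer (or exact halves), so certified optima are
solver-independent rationals.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from fractions import Fraction
from pathlib import Path

from . import cmcs, lp
from .model import (
    MediumSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_dye_pathway_extension,
    apply_medium,
    apply_reaction_knockouts,
    write_sbml,
)

_NUM_TOL = 1e-7


class ToyGenerationError(RuntimeError):
    """The requested toy specification failed generation-time certification."""


@dataclass
class ToySpec:
    """Parameters of the toy coupling network.

    ``nadh_per_aromatic`` is the NADH consumed per aromatic substrate
    (azoreductase-like), ``nadh_per_sugar`` the NADH produced per sugar
    (glycolysis-like), ``product_nadh_yield`` the NADH regenerated per product
    (polyketide-tailoring-like). The planted cut set is the set of alternative
    NADH-source reactions; knocking all of them out couples the product in
    aromatic mode. Rates are mmol gDW^-1 h^-1; all stoichiometry integers.
    """

    substrate_mode: str = "aromatic"  # sugar | aromatic | both
    nadh_per_aromatic: int = 1
    nadh_per_sugar: int = 3
    product_nadh_yield: int = 2
    primary_source_nadh_yield: int = 3
    planted_cutset_size: int = 2
    uptake_limit: int = 10
    sugar_uptake_limit: int = 10
    maintenance: int = 1
    biomass_atp_cost: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.substrate_mode not in ("sugar", "aromatic", "both"):
            raise ValueError(f"unknown substrate_mode {self.substrate_mode!r}")
        ints = (
            self.nadh_per_aromatic,
            self.nadh_per_sugar,
            self.product_nadh_yield,
            self.primary_source_nadh_yield,
            self.planted_cutset_size,
            self.uptake_limit,
            self.sugar_uptake_limit,
            self.maintenance,
            self.biomass_atp_cost,
        )
        if any(not isinstance(v, int) or v < 0 for v in ints):
            raise ValueError("all stoichiometric integers must be >= 0")
        if self.planted_cutset_size < 1:
            raise ValueError("planted_cutset_size must be >= 1")
        # structural conditions the certification relies on
        if self.product_nadh_yield <= self.nadh_per_aromatic:
            raise ValueError(
                "product pathway must regenerate more NADH than aromatic "
                "catabolism consumes, else coupling is impossible"
            )
        if self.primary_source_nadh_yield <= max(
            self.product_nadh_yield, self.nadh_per_aromatic + 1
        ):
            raise ValueError(
                "the primary NADH source must have the strictly highest yield"
            )
        if self.substrate_mode in ("sugar", "both"):
            if self.nadh_per_sugar <= self.biomass_atp_cost:
                raise ValueError(
                    "sugar catabolism must over-supply NADH relative to the "
                    "biomass ATP cost (excess redox is what makes sugar "
                    "substrates uncouplable); raise nadh_per_sugar"
                )
            if (self.nadh_per_sugar - self.biomass_atp_cost) * self.sugar_uptake_limit < self.maintenance:
                raise ValueError("sugar uptake limit too small to cover maintenance")
        if self.uptake_limit * (self.primary_source_nadh_yield - self.nadh_per_aromatic) <= self.maintenance:
            raise ValueError("uptake limit too small to sustain growth")


@dataclass
class ToyModelBundle:
    model: MetabolicModel
    spec: ToySpec
    metadata: dict

    @property
    def planted_cutset(self) -> frozenset[str]:
        return frozenset(self.metadata["planted_cutset"])


def sample_toy_spec(substrate_mode: str, seed: int) -> ToySpec:
    """A randomized but always-certifiable toy specification."""
    rng = random.Random(seed)
    c = rng.choice([1, 2])
    yp = c + rng.choice([1, 2])
    y1 = max(yp, c + 1) + rng.choice([1, 2])
    e = rng.choice([2, 3])
    return ToySpec(
        substrate_mode=substrate_mode,
        nadh_per_aromatic=c,
        nadh_per_sugar=e + rng.choice([1, 2]),
        product_nadh_yield=yp,
        primary_source_nadh_yield=y1,
        planted_cutset_size=rng.choice([1, 2, 3]),
        uptake_limit=rng.choice([8, 10, 12]),
        sugar_uptake_limit=rng.choice([8, 10]),
        maintenance=1,
        biomass_atp_cost=e,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# toy construction
# ---------------------------------------------------------------------------

def _toy_reactions(spec: ToySpec) -> list[Reaction]:
    c, ys = spec.nadh_per_aromatic, spec.nadh_per_sugar
    yp, y1 = spec.product_nadh_yield, spec.primary_source_nadh_yield
    k = spec.planted_cutset_size
    rxns: list[Reaction] = []
    if spec.substrate_mode in ("aromatic", "both"):
        rxns += [
            Reaction("EX_suba_e", {"suba_e": -1}, -spec.uptake_limit, 1000),
            Reaction("SUBAt1", {"suba_e": -1, "suba_p": 1}, -1000, 1000),
            Reaction("SUBAt2", {"suba_p": -1, "suba_c": 1}, -1000, 1000),
            Reaction(
                "CATA",
                {"suba_c": -1, "nadh_c": -c, "nad_c": c, "cc_c": 1},
                0, 1000, gpr="gCATA",
            ),
        ]
    if spec.substrate_mode in ("sugar", "both"):
        rxns += [
            Reaction("EX_subg_e", {"subg_e": -1}, -spec.sugar_uptake_limit, 1000),
            Reaction("SUBGt1", {"subg_e": -1, "subg_p": 1}, -1000, 1000),
            Reaction("SUBGt2", {"subg_p": -1, "subg_c": 1}, -1000, 1000),
            Reaction(
                "CATG",
                {"subg_c": -1, "nad_c": -ys, "nadh_c": ys, "cc_c": 1},
                0, 1000, gpr="gCATG",
            ),
        ]
    # planted NADH sources: NS1 is the high-yield primary (TCA-like, with an
    # isoenzyme pair), NS2.. are lower-yield alternatives (formate-DH-like)
    for i in range(1, k + 1):
        yield_i = y1 if i == 1 else c + 1
        gpr = "gNS1a or gNS1b" if i == 1 else f"gNS{i}"
        rxns.append(
            Reaction(
                f"NS{i}",
                {"cc_c": -1, "nad_c": -yield_i, "nadh_c": yield_i, "co2_c": 1},
                0, 1000, gpr=gpr,
            )
        )
    rxns += [
        Reaction(
            "PKS",
            {"cc_c": -1, "nad_c": -yp, "nadh_c": yp, "prod_c": 1},
            0, 1000, gpr="gPKSa and gPKSb",
        ),
        Reaction(
            "RESP",
            {"nadh_c": -1, "adp_c": -1, "nad_c": 1, "atp_c": 1},
            0, 1000, gpr="gRESP",
        ),
        Reaction("ATPM", {"atp_c": -1, "adp_c": 1}, spec.maintenance, 1000),
        Reaction(
            "BIOMASS",
            {"cc_c": -1, "atp_c": -spec.biomass_atp_cost,
             "adp_c": spec.biomass_atp_cost},
            0, 1000,
        ),
        Reaction("PRODt", {"prod_c": -1, "prod_e": 1}, 0, 1000),
        Reaction("EX_prod_e", {"prod_e": -1}, 0, 1000),
        Reaction("CO2t", {"co2_c": -1, "co2_e": 1}, -1000, 1000),
        Reaction("EX_co2_e", {"co2_e": -1}, 0, 1000),
    ]
    return rxns


def _toy_metabolites(reactions: list[Reaction]) -> list[Metabolite]:
    ids: dict[str, None] = {}
    for rxn in reactions:
        for met in rxn.stoichiometry:
            ids.setdefault(met)
    return [Metabolite(m, compartment=m.rsplit("_", 1)[-1]) for m in ids]


def _toy_optima(spec: ToySpec) -> dict[str, Fraction]:
    """Closed-form optima of the toy LP, exact rational arithmetic."""
    c = Fraction(spec.nadh_per_aromatic)
    ys = Fraction(spec.nadh_per_sugar)
    yp = Fraction(spec.product_nadh_yield)
    y1 = Fraction(spec.primary_source_nadh_yield)
    e = Fraction(spec.biomass_atp_cost)
    m0 = Fraction(spec.maintenance)
    Ua = Fraction(spec.uptake_limit)
    Ug = Fraction(spec.sugar_uptake_limit)
    out: dict[str, Fraction] = {}
    if spec.substrate_mode == "aromatic":
        out["max_growth"] = (Ua * (y1 - c) - m0) / (y1 + e)
        out["max_product"] = Ua
        out["coupled_max_growth"] = (Ua * (yp - c) - m0) / (yp + e)
        out["coupled_min_product"] = m0 / (yp - c)
    elif spec.substrate_mode == "sugar":
        # ys > e: sugar alone covers biomass ATP plus maintenance
        out["max_growth"] = Ug
        out["max_product"] = Ug
    else:  # both; the planted set includes the sugar catabolism reaction,
        # so the coupled phenotype runs on the aromatic substrate alone
        out["max_growth"] = ((y1 - c) * Ua + (y1 + ys) * Ug - m0) / (y1 + e)
        out["max_product"] = Ua + Ug
        out["coupled_max_growth"] = (Ua * (yp - c) - m0) / (yp + e)
        out["coupled_min_product"] = m0 / (yp - c)
    return out


def _toy_growth_vector(spec: ToySpec, optima: dict[str, Fraction]) -> dict[str, Fraction]:
    """An exactly balanced rational flux vector attaining max growth."""
    c = Fraction(spec.nadh_per_aromatic)
    ys = Fraction(spec.nadh_per_sugar)
    y1 = Fraction(spec.primary_source_nadh_yield)
    e = Fraction(spec.biomass_atp_cost)
    m0 = Fraction(spec.maintenance)
    Ua = Fraction(spec.uptake_limit)
    Ug = Fraction(spec.sugar_uptake_limit)
    b = optima["max_growth"]
    v: dict[str, Fraction] = {"BIOMASS": b, "ATPM": m0, "RESP": e * b + m0}
    if spec.substrate_mode == "aromatic":
        ns1 = ((e + c) * b + m0) / (y1 - c)
        v.update(
            {"NS1": ns1, "CATA": Ua, "SUBAt1": Ua, "SUBAt2": Ua,
             "EX_suba_e": -Ua}
        )
    elif spec.substrate_mode == "sugar":
        ns1 = Fraction(0)
        v.update(
            {"NS1": ns1, "CATG": Ug, "SUBGt1": Ug, "SUBGt2": Ug,
             "EX_subg_e": -Ug, "RESP": ys * Ug, "ATPM": (ys - e) * Ug}
        )
    else:
        ns1 = Ua + Ug - b
        v.update(
            {"NS1": ns1, "CATA": Ua, "SUBAt1": Ua, "SUBAt2": Ua,
             "EX_suba_e": -Ua, "CATG": Ug, "SUBGt1": Ug, "SUBGt2": Ug,
             "EX_subg_e": -Ug}
        )
    v["CO2t"] = ns1
    v["EX_co2_e"] = ns1
    return v


def _check_rational_vector(model: MetabolicModel, vector: dict[str, Fraction]) -> None:
    """Exact steady-state and bounds check (Fraction arithmetic, no solver)."""
    balance: dict[str, Fraction] = {m: Fraction(0) for m in model.metabolites}
    for rid, rxn in model.reactions.items():
        flux = vector.get(rid, Fraction(0))
        lbf, ubf = Fraction(rxn.lower_bound), Fraction(rxn.upper_bound)
        if not lbf <= flux <= ubf:
            raise ToyGenerationError(f"certified flux of {rid} violates bounds")
        for met, coef in rxn.stoichiometry.items():
            balance[met] += Fraction(coef) * flux
    bad = {m: val for m, val in balance.items() if val != 0}
    if bad:
        raise ToyGenerationError(f"certified flux vector not balanced: {bad}")


def make_toy_model(spec: ToySpec | None = None) -> ToyModelBundle:
    """Build and certify a toy coupling model.

    Certification (all at generation time): the closed-form rational optima
    agree with fresh LP solves; the stored rational growth vector satisfies
    S v = 0 exactly; and the exhaustive cut-set oracle confirms the planted
    coupling dichotomy (aromatic/both: exactly the planted set; sugar: none)
    for all candidate subsets up to planted size + 1.
    """
    spec = spec or ToySpec()
    spec.validate()
    reactions = _toy_reactions(spec)
    model = MetabolicModel(
        model_id=f"toy_{spec.substrate_mode}_{spec.seed}",
        metabolites=_toy_metabolites(reactions),
        reactions=reactions,
        objective_reaction="BIOMASS",
    )
    model.validate()

    optima = _toy_optima(spec)
    growth_vec = _toy_growth_vector(spec, optima)
    _check_rational_vector(model, growth_vec)

    res = lp.fba(model, objective="BIOMASS")
    if not res.optimal or abs(res.objective_value - float(optima["max_growth"])) > _NUM_TOL:
        raise ToyGenerationError(
            f"LP growth optimum {res.objective_value} disagrees with the "
            f"analytic value {float(optima['max_growth'])}"
        )
    prod = lp.fba(model, objective="EX_prod_e")
    if not prod.optimal or abs(prod.objective_value - float(optima["max_product"])) > _NUM_TOL:
        raise ToyGenerationError("LP product optimum disagrees with analytic value")

    planted = frozenset(f"NS{i}" for i in range(1, spec.planted_cutset_size + 1))
    if spec.substrate_mode == "both":
        # the sugar route must also be severed, or its excess NADH rescues
        # growth without product
        planted |= {"CATG"}
    target, desired = cmcs.build_regions(
        model, "EX_prod_e", "BIOMASS", min_biomass_pct=0, min_product_pct=0
    )
    candidates = cmcs.preprocess_targets(model)
    oracle = cmcs.exhaustive_mcs(
        model, candidates, target, desired, max_size=len(planted) + 1
    )
    families = {cs.reactions for cs in oracle}
    if spec.substrate_mode == "sugar":
        if families:
            raise ToyGenerationError(
                f"sugar-mode toy unexpectedly admits cut sets: {families}"
            )
    else:
        if families != {planted}:
            raise ToyGenerationError(
                f"oracle cut sets {families} differ from planted {planted}"
            )
        coupled = apply_reaction_knockouts(model, planted)
        cres = lp.fba(coupled, objective="BIOMASS")
        if abs(cres.objective_value - float(optima["coupled_max_growth"])) > _NUM_TOL:
            raise ToyGenerationError("coupled growth optimum failed certification")

    metadata = {
        "spec": asdict(spec),
        "optima": {k: str(v) for k, v in optima.items()},
        "optima_float": {k: float(v) for k, v in optima.items()},
        "certified_growth_vector": {k: str(v) for k, v in growth_vec.items()},
        "planted_cutset": sorted(planted) if spec.substrate_mode != "sugar" else [],
        "candidates": sorted(candidates),
        "n_reactions": len(model.reactions),
    }
    return ToyModelBundle(model, spec, metadata)


# ---------------------------------------------------------------------------
# demo central-carbon model (named metabolites, dye pathway graftable)
# ---------------------------------------------------------------------------

def make_demo_model(include_dye_pathway: bool = True) -> MetabolicModel:
    """A small named-metabolite production-host emulation.

    The base network has a glucose entry (lumped glycolysis), pyruvate
    dehydrogenase, a lumped TCA cycle, catechol meta-cleavage (native aromatic
    catabolism), oxidative phosphorylation with an O2 exchange, acetyl-CoA
    carboxylase, ATP maintenance (0.92 mmol gDW^-1 h^-1), and a biomass
    reaction drawing acetyl-CoA, pyruvate, and ATP. With
    ``include_dye_pathway`` the bundled methyl-red block and the synthetic
    actinorhodin block are grafted on, yielding a host that can grow on MR
    and secrete ACT. All exchanges start closed for uptake; apply a medium.
    """
    rxns = [
        Reaction("EX_glc__D_e", {"glc__D_e": -1}, 0, 1000),
        Reaction("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, -1000, 1000),
        Reaction(
            "GLYC",
            {"glc__D_c": -1, "nad_c": -2, "adp_c": -2,
             "pyr_c": 2, "nadh_c": 2, "atp_c": 2},
            0, 1000, gpr="glk",
        ),
        Reaction(
            "PDH",
            {"pyr_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
            0, 1000, gpr="aceE and aceF and lpdG",
        ),
        Reaction(
            "TCA",
            {"accoa_c": -1, "nad_c": -3, "adp_c": -1,
             "co2_c": 2, "nadh_c": 3, "atp_c": 1},
            0, 1000, gpr="gltA",
        ),
        Reaction(
            "CATDO",
            {"catechol_c": -1, "o2_c": -1, "nad_c": -2,
             "pyr_c": 1, "accoa_c": 1, "co2_c": 1, "nadh_c": 2},
            0, 1000, gpr="xylE",
        ),
        Reaction(
            "OXPHOS",
            {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2,
             "nad_c": 1, "atp_c": 2},
            0, 1000, gpr="nuoA",
        ),
        Reaction(
            "ACCOAC",
            {"accoa_c": -1, "atp_c": -1, "co2_c": -1,
             "malcoa_c": 1, "adp_c": 1},
            0, 1000, gpr="accA and accB",
        ),
        Reaction("ATPM", {"atp_c": -1, "adp_c": 1}, 0.92, 1000),
        Reaction(
            "BIOMASS",
            {"accoa_c": -1, "pyr_c": -1, "atp_c": -6, "adp_c": 6},
            0, 1000,
        ),
        Reaction("O2t", {"o2_e": -1, "o2_c": 1}, -1000, 1000),
        Reaction("EX_o2_e", {"o2_e": -1}, 0, 1000),
        Reaction("CO2t", {"co2_c": -1, "co2_e": 1}, -1000, 1000),
        Reaction("EX_co2_e", {"co2_e": -1}, 0, 1000),
        Reaction("NH4t", {"nh4_c": -1, "nh4_e": 1}, -1000, 1000),
        Reaction("EX_nh4_e", {"nh4_e": -1}, 0, 1000),
        Reaction("Ht_ep", {"h_e": -1, "h_p": 1}, -1000, 1000),
        Reaction("Ht_pc", {"h_p": -1, "h_c": 1}, -1000, 1000),
        Reaction("EX_h_e", {"h_e": -1}, 0, 1000),
    ]
    mets = _toy_metabolites(rxns)
    model = MetabolicModel(
        model_id="demo_host_base",
        metabolites=mets,
        reactions=rxns,
        objective_reaction="BIOMASS",
    )
    if include_dye_pathway:
        model = apply_dye_pathway_extension(model)
        model.id = "demo_host_mr_act"
    model.validate()
    return model


def demo_medium(
    carbon: str = "mr",
    mr_uptake: float = 1000.0,
    glc_uptake: float = 10.0,
    o2_uptake: float = 30.0,
) -> MediumSpec:
    """Minimal-medium specification for the demo host.

    ``carbon``: "mr" (dye only, uptake deliberately unconstrained at 1000),
    "glc", or "glc_mr". O2 defaults to 30 mmol gDW^-1 h^-1 (aerobic);
    protons are freely exchangeable.
    """
    limits: dict[str, float] = {"EX_o2_e": o2_uptake, "EX_h_e": 1000.0}
    if carbon in ("mr", "glc_mr"):
        limits["EX_mr_e"] = mr_uptake
    if carbon in ("glc", "glc_mr"):
        limits["EX_glc__D_e"] = glc_uptake
    if carbon not in ("mr", "glc", "glc_mr"):
        raise ValueError(f"unknown carbon configuration {carbon!r}")
    return MediumSpec(uptake_limits=limits, name=f"M9_{carbon}")


def gapfill_candidates(include_fill: bool = True) -> list[Reaction]:
    """Candidate reactions for the gap-filling demonstration.

    The true missing link (anthranilate dioxygenase) plus decoy reactions,
    each draining a metabolite into a fresh dead end so that none of them can
    carry steady-state flux.
    """
    from .model import act_pathway_reactions

    decoys = [
        Reaction(f"DECOY{i}", {met: -1, f"dead{i}_c": 1}, 0, 1000)
        for i, met in enumerate(
            ["anth_c", "catechol_c", "accoa_c", "pyr_c", "nadh_c"], start=1
        )
    ]
    if not include_fill:
        return decoys
    anthdo = [r for r in act_pathway_reactions() if r.id == "AnthDO"]
    return anthdo + decoys


# ---------------------------------------------------------------------------
# fixture suite on disk
# ---------------------------------------------------------------------------

def write_fixture_suite(directory: str | Path, seed: int = 0) -> list[Path]:
    """Write SBML fixtures, media, candidate tables, and expected-value
    metadata for the test suite. Deterministic given the seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for mode in ("aromatic", "sugar", "both"):
        bundle = make_toy_model(ToySpec(substrate_mode=mode, seed=seed))
        sbml = directory / f"toy_{mode}.xml"
        write_sbml(bundle.model, sbml)
        meta = directory / f"toy_{mode}.meta.json"
        meta.write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
        written += [sbml, meta]

    demo = make_demo_model()
    demo_path = directory / "demo_host.xml"
    write_sbml(demo, demo_path)
    written.append(demo_path)

    media = {
        name: demo_medium(name).uptake_limits for name in ("mr", "glc", "glc_mr")
    }
    media_path = directory / "demo_media.json"
    media_path.write_text(json.dumps(media, indent=2, sort_keys=True))
    written.append(media_path)

    cand_path = directory / "gapfill_candidates.tsv"
    lines = ["# gap-filling candidates: id\tequation\tlb\tub\tgpr"]
    for rxn in gapfill_candidates():
        eq_parts_l, eq_parts_r = [], []
        for met, coef in sorted(rxn.stoichiometry.items()):
            base, comp = met.rsplit("_", 1)
            token = f"{abs(coef):g} {base}[{comp}]" if abs(coef) != 1 else f"{base}[{comp}]"
            (eq_parts_l if coef < 0 else eq_parts_r).append(token)
        eq = f"{' + '.join(eq_parts_l)} --> {' + '.join(eq_parts_r)}"
        lines.append(
            f"{rxn.id}\t{eq}\t{rxn.lower_bound:g}\t{rxn.upper_bound:g}\t{rxn.gpr.to_string()}"
        )
    cand_path.write_text("\n".join(lines) + "\n")
    written.append(cand_path)
    return written
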