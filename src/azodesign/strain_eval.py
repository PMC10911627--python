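"""Post-cut-set strain evaluation.

Covers the steps between a raw reaction-knockout suggestion and a reportable
strain design: resolving knockouts to gene sets via GPR logic and checking
that the gene-level phenotype agrees with the reaction-level one; computing
design metrics (substrate uptake, growth, product flux, product yield, the
minimum guaranteed yield, and the biomass-product coupled yield BPCY =
yield x growth); and pathway-utilization tables that attribute the production
of key central-carbon metabolites to specific reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import lp
from .cmcs import CutSet, InterventionRegion, verify_cut_set
from .model import (
    MediumSpec,
    MetabolicModel,
    apply_gene_knockouts,
    apply_medium,
    apply_reaction_knockouts,
)

MAX_REASONABLE_KNOCKOUTS = 25

#: 23 representative metabolites of central carbon metabolism (BiGG-style
#: cytosolic ids): glycolysis/gluconeogenesis, TCA cycle, EMP/ED/PP pathways,
#: the glyoxylate shunt, aromatic catabolism, and amino-acid biosynthesis.
KEY_METABOLITES: tuple[str, ...] = (
    "accoa_c",      # acetyl-CoA
    "oaa_c",        # oxaloacetate
    "pyr_c",        # pyruvate
    "pep_c",        # phosphoenolpyruvate
    "akg_c",        # alpha-ketoglutarate
    "fum_c",        # fumarate
    "cit_c",        # citrate
    "fdp_c",        # fructose-1,6-bisphosphate
    "g6p_c",        # glucose-6-phosphate
    "g3p_c",        # glyceraldehyde-3-phosphate
    "3pg_c",        # 3-phosphoglycerate
    "6pgc_c",       # 6-phosphogluconate
    "2ddg6p_c",     # 2-dehydro-3-deoxy-D-gluconate-6-phosphate
    "glx_c",        # glyoxylate
    "acald_c",      # acetaldehyde
    "ru5p__D_c",    # ribulose-5-phosphate
    "xu5p__D_c",    # xylulose-5-phosphate
    "dhap_c",       # dihydroxyacetone phosphate
    "glyc__R_c",    # D-glycerate
    "glu__L_c",     # glutamate
    "ser__L_c",     # serine
    "asp__L_c",     # aspartate
    "leu__L_c",     # leucine
)


@dataclass
class GeneCheckResult:
    genes: frozenset[str]
    agreement: bool
    disabled_reactions: frozenset[str] = frozenset()


@dataclass
class DesignReport:
    design_id: str
    status: str  # optimal | infeasible
    substrate_uptake: float | None = None
    growth: float | None = None
    product_flux: float | None = None
    yield_at_optimum_growth: float | None = None
    min_guaranteed_yield: float | None = None
    min_guaranteed_yield_alt: float | None = None
    bpcy: float | None = None
    n_reaction_knockouts: int = 0
    n_gene_knockouts: int = 0
    gene_agreement: bool | None = None
    knockout_size_ok: bool | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PathwayUtilization:
    """Per key-metabolite production totals and producing reactions."""

    totals: dict[str, float] = field(default_factory=dict)
    producers: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    directions: dict[str, dict[str, str]] = field(default_factory=dict)

    def __getitem__(self, met_id: str) -> float:
        return self.totals[met_id]


# ---------------------------------------------------------------------------
# gene-level knockout agreement
# ---------------------------------------------------------------------------

def resolve_knockout_genes(
    model: MetabolicModel, reactions: Iterable[str]
) -> frozenset[str]:
    """Map reaction knockouts to a gene-knockout set.

    Per-reaction policy: among the minimal gene sets that falsify the GPR,
    prefer the one using the fewest pleiotropic genes (genes appearing in the
    GPR of any other reaction), then the smallest, then lexicographic order.
    For isoenzymes (an OR rule) this knocks out all encoding genes; for a
    complex (an AND rule) a single subunit gene suffices.
    """
    pleiotropy: dict[str, int] = {}
    for rxn in model.reactions.values():
        for g in rxn.gpr.genes():
            pleiotropy[g] = pleiotropy.get(g, 0) + 1

    genes: set[str] = set()
    for rid in reactions:
        rxn = model.reactions[rid]
        if rxn.gpr.is_empty:
            raise ValueError(
                f"reaction {rid!r} has no gene association; it should have been "
                "excluded during knockout-candidate preprocessing"
            )
        options = rxn.gpr.minimal_knockout_sets()
        options.sort(
            key=lambda s: (
                sum(1 for g in s if pleiotropy.get(g, 0) > 1),
                len(s),
                tuple(sorted(s)),
            )
        )
        genes |= options[0]
    return frozenset(genes)


def gene_level_check(
    model: MetabolicModel,
    cutset: CutSet | Iterable[str],
    target: InterventionRegion,
    desired: InterventionRegion,
) -> GeneCheckResult:
    """Resolve a reaction cut set to genes and test phenotype agreement.

    Agreement holds when the gene-knocked model blocks the target region and
    keeps the desired region feasible exactly as the reaction-knocked model
    does. A pleiotropic gene that collaterally disables an essential reaction
    breaks agreement.
    """
    reactions = set(cutset.reactions) if isinstance(cutset, CutSet) else set(cutset)
    genes = resolve_knockout_genes(model, reactions)
    gene_model = apply_gene_knockouts(model, genes)
    disabled = frozenset(
        rid
        for rid, rxn in gene_model.reactions.items()
        if rxn.upper_bound == rxn.lower_bound == 0.0
        and not (
            model.reactions[rid].upper_bound == model.reactions[rid].lower_bound == 0.0
        )
    )
    rxn_flags = verify_cut_set(model, reactions, target, desired)
    t_cons, d_cons = target.as_lp_constraints(), desired.as_lp_constraints()
    gene_flags = {
        "target_blocked": not lp.region_feasible(gene_model, t_cons),
        "desired_feasible": lp.region_feasible(gene_model, d_cons),
    }
    agreement = (
        gene_flags["target_blocked"] == rxn_flags["target_blocked"]
        and gene_flags["desired_feasible"] == rxn_flags["desired_feasible"]
        and disabled >= reactions
    )
    result = GeneCheckResult(genes, agreement, disabled)
    if isinstance(cutset, CutSet):
        cutset.genes = genes
        cutset.verified["gene_agreement"] = agreement
    return result


# ---------------------------------------------------------------------------
# design metrics
# ---------------------------------------------------------------------------

def evaluate_design(
    model: MetabolicModel,
    cutset: CutSet | Iterable[str],
    substrate_exchange: str,
    product_exchange: str,
    medium: MediumSpec | None = None,
    objective: str | None = None,
    design_id: str = "design",
    genes: Iterable[str] | None = None,
) -> DesignReport:
    """Simulate a knockout design and compute its reportable metrics.

    Growth, product flux, and substrate uptake come from a parsimonious FBA
    optimum under the biomass objective. Product yield is product flux over
    absolute substrate uptake; BPCY is yield times growth. The minimum
    guaranteed yield is computed by a two-stage LP: minimize the product flux
    subject to (near-)zero growth remaining feasible, then maximize substrate
    uptake at that product flux (worst-case yield); the alternative reading,
    dividing by the optimum-growth uptake, is reported alongside.
    """
    reactions = set(cutset.reactions) if isinstance(cutset, CutSet) else set(cutset)
    objective = objective or model.objective_reaction
    work = apply_medium(model, medium) if medium is not None else model
    work = apply_reaction_knockouts(work, reactions) if reactions else work
    for rid in (substrate_exchange, product_exchange):
        if rid not in work.reactions:
            raise KeyError(f"reaction {rid!r} not in model")

    gene_set = frozenset(genes) if genes is not None else (
        cutset.genes if isinstance(cutset, CutSet) else frozenset()
    )
    report = DesignReport(
        design_id=design_id,
        status="infeasible",
        n_reaction_knockouts=len(reactions),
        n_gene_knockouts=len(gene_set),
        gene_agreement=(
            cutset.verified.get("gene_agreement")
            if isinstance(cutset, CutSet)
            else None
        ),
    )

    opt = lp.fba(work, objective=objective, tie_break=True)
    if not opt.optimal:
        return report

    def clean(v: float) -> float:
        return 0.0 if abs(v) < 1e-9 else v

    growth = clean(opt.objective_value)
    uptake = clean(abs(opt.fluxes[substrate_exchange]))
    product = clean(opt.fluxes[product_exchange])
    report.status = "optimal"
    report.growth = growth
    report.substrate_uptake = uptake
    report.product_flux = product
    report.yield_at_optimum_growth = product / uptake if uptake > 0 else 0.0
    report.bpcy = report.yield_at_optimum_growth * growth
    report.knockout_size_ok = len(gene_set or reactions) <= MAX_REASONABLE_KNOCKOUTS

    # stage 1: worst-case product flux with viability maintained
    eps_growth = 1e-6 * max(growth, 1e-3)
    stage1 = lp.fba(
        work,
        objective=product_exchange,
        direction="min",
        constraints=[({objective: 1.0}, ">=", eps_growth)],
    )
    if stage1.optimal:
        min_prod = max(stage1.objective_value, 0.0)
        # stage 2: the uptake that worst case can ride on
        stage2 = lp.fba(
            work,
            objective=substrate_exchange,
            direction="min",  # most-negative exchange flux = max uptake
            constraints=[
                ({objective: 1.0}, ">=", eps_growth),
                ({product_exchange: 1.0}, "<=", min_prod + 1e-9),
            ],
        )
        if stage2.optimal and abs(stage2.objective_value) > 0:
            report.min_guaranteed_yield = min_prod / abs(stage2.objective_value)
        if uptake > 0:
            report.min_guaranteed_yield_alt = min_prod / uptake
    return report


def table3(reports: Sequence[DesignReport]) -> pd.DataFrame:
    """Render design reports side by side (one row per design)."""
    cols = [
        "design_id",
        "substrate_uptake",
        "growth",
        "product_flux",
        "min_guaranteed_yield",
        "yield_at_optimum_growth",
        "bpcy",
        "n_reaction_knockouts",
        "n_gene_knockouts",
        "gene_agreement",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in reports])


# ---------------------------------------------------------------------------
# pathway utilization
# ---------------------------------------------------------------------------

def pathway_utilization(
    model: MetabolicModel,
    knockouts: Iterable[str] = (),
    medium: MediumSpec | None = None,
    objective: str | None = None,
    key_metabolites: Sequence[str] = KEY_METABOLITES,
) -> PathwayUtilization:
    """Total producing flux and producer identities for each key metabolite.

    Uses the parsimonious FBA flux vector under the given objective (growth by
    default, emulating a cell optimizing biomass); for each metabolite the
    positive S_ij * v_j contributions are summed and attributed to reactions,
    with the flux direction relative to the reaction's forward sense recorded.
    """
    work = apply_medium(model, medium) if medium is not None else model
    work = apply_reaction_knockouts(work, set(knockouts)) if knockouts else work
    missing = [m for m in key_metabolites if m not in work.metabolites]
    if missing:
        raise KeyError(f"key metabolites absent from model: {missing}")
    res = lp.fba(work, objective=objective, tie_break=True)
    if not res.optimal:
        raise lp.InfeasibleRegionError("no optimal flux state for utilization analysis")
    report = lp.flux_sum(work, res, metabolites=key_metabolites)
    out = PathwayUtilization()
    for met in key_metabolites:
        producers = report.producing[met]
        out.totals[met] = sum(rate for _, rate in producers)
        out.producers[met] = producers
        out.directions[met] = {
            rid: ("forward" if res.fluxes[rid] >= 0 else "reverse")
            for rid, _ in producers
        }
    return out
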