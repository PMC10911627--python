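"""FBA, FVA, envelopes, flux-sums: unit checks, brute-force oracles, and
cross-validation against an independent solver stack (cobrapy/GLPK)."""

import itertools

import numpy as np
import pytest

from azodesign import lp
from azodesign.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_reaction_knockouts,
    write_sbml,
)


def chain_model():
    """Source -> A -> B -> sink, all bounds [0, 10]; optimum is 10 by hand."""
    return MetabolicModel(
        "chain",
        metabolites=[Metabolite("A_c"), Metabolite("B_c")],
        reactions=[
            Reaction("SRC", {"A_c": 1}, 0, 10),
            Reaction("CONV", {"A_c": -1, "B_c": 1}, 0, 10),
            Reaction("SINK", {"B_c": -1}, 0, 10),
        ],
        objective_reaction="SINK",
    )


def branch_model():
    """Six reactions, two routes with different capacities; used by the
    vertex-enumeration oracle."""
    return MetabolicModel(
        "branch",
        metabolites=[Metabolite("A_c"), Metabolite("B_c"), Metabolite("C_c")],
        reactions=[
            Reaction("SRC", {"A_c": 1}, 0, 8),
            Reaction("R1", {"A_c": -1, "B_c": 1}, 0, 5),
            Reaction("R2", {"A_c": -1, "C_c": 1}, 0, 4),
            Reaction("J1", {"B_c": -1, "C_c": 1}, -3, 3),
            Reaction("SINK_C", {"C_c": -1}, 0, 6),
            Reaction("SINK_B", {"B_c": -1}, 0, 2),
        ],
        objective_reaction="SINK_C",
    )


def enumerate_vertices(model):
    """All basic feasible solutions of {S v = 0, lb <= v <= ub} by fixing
    subsets of fluxes at their bounds and solving the remaining square system.
    Independent of the LP solver path."""
    S, _, rxn_ids = model.stoichiometric_matrix()
    S = S.toarray()
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    rank = np.linalg.matrix_rank(S)
    vertices = []
    for fixed in itertools.combinations(range(n), n - rank):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if np.linalg.matrix_rank(A) < len(free):
            continue
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            b = -S[:, fixed] @ np.array(bounds_choice)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.linalg.norm(A @ sol - b) > 1e-9:
                continue
            v = np.zeros(n)
            v[free] = sol
            v[list(fixed)] = bounds_choice
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                vertices.append(v)
    assert vertices, "polytope has at least one vertex"
    return np.array(vertices), rxn_ids


def to_cobra(model, tmp_path, name="x.xml"):
    import cobra

    path = tmp_path / name
    write_sbml(model, path)
    return cobra.io.read_sbml_model(str(path))


# -- FBA ---------------------------------------------------------------------

def test_fba_chain_matches_hand_lp():
    res = lp.fba(chain_model(), objective="SINK")
    assert res.optimal
    assert res.objective_value == pytest.approx(10.0, abs=1e-9)


def test_fba_all_exchanges_closed_is_zero(aromatic_toy):
    m = aromatic_toy.model.copy()
    m.reactions["EX_suba_e"].lower_bound = 0.0
    m.reactions["ATPM"].lower_bound = 0.0  # keep the region non-empty
    res = lp.fba(m, objective="BIOMASS")
    assert res.optimal and abs(res.objective_value) < 1e-9


def test_fba_status_infeasible_and_unbounded():
    infeasible = MetabolicModel(
        "inf",
        metabolites=[Metabolite("atp_c")],
        reactions=[Reaction("ATPM", {"atp_c": -1}, 1, 10)],
        objective_reaction="ATPM",
    )
    assert lp.fba(infeasible).status == "infeasible"

    unbounded = MetabolicModel(
        "unb",
        metabolites=[Metabolite("A_c"), Metabolite("B_c")],
        reactions=[
            Reaction("F", {"A_c": -1, "B_c": 1}, -np.inf, np.inf),
            Reaction("G", {"B_c": -1, "A_c": 1}, -np.inf, np.inf),
        ],
        objective_reaction="F",
    )
    assert lp.fba(unbounded).status == "unbounded"


def test_fba_matches_cobra_on_fixtures(aromatic_toy, demo_mr, tmp_path):
    """Dual-route check: same SBML solved by cobrapy/GLPK."""
    for model, obj in ((aromatic_toy.model, "BIOMASS"), (demo_mr, "BIOMASS"),
                       (demo_mr, "ACTt")):
        cm = to_cobra(model, tmp_path, f"{model.id}_{obj}.xml")
        cm.objective = obj
        mine = lp.fba(model, objective=obj).objective_value
        assert mine == pytest.approx(cm.slim_optimize(), rel=1e-6)


def test_objective_invariant_to_reaction_order(demo_mr):
    shuffled = MetabolicModel(
        "shuffled",
        metabolites=list(demo_mr.metabolites.values()),
        reactions=[demo_mr.reactions[r] for r in sorted(demo_mr.reactions, reverse=True)],
        objective_reaction=demo_mr.objective_reaction,
    )
    a = lp.fba(demo_mr, objective="BIOMASS").objective_value
    b = lp.fba(shuffled, objective="BIOMASS").objective_value
    assert a == pytest.approx(b, rel=1e-6)


# -- FVA ---------------------------------------------------------------------

def test_fva_matches_vertex_enumeration_oracle():
    model = branch_model()
    vertices, rxn_ids = enumerate_vertices(model)
    ranges = lp.fva(model)
    for j, rid in enumerate(rxn_ids):
        lo, hi = ranges[rid]
        assert lo == pytest.approx(vertices[:, j].min(), abs=1e-7)
        assert hi == pytest.approx(vertices[:, j].max(), abs=1e-7)


def test_fva_matches_cobra(aromatic_toy, tmp_path):
    from cobra.flux_analysis import flux_variability_analysis

    cm = to_cobra(aromatic_toy.model, tmp_path)
    cm.objective = "BIOMASS"
    targets = ["EX_prod_e", "NS1", "PKS", "RESP"]
    theirs = flux_variability_analysis(cm, reaction_list=targets, fraction_of_optimum=0.9)
    mine = lp.fva(aromatic_toy.model, reactions=targets, fix_objective_fraction=0.9,
                  objective="BIOMASS")
    for rid in targets:
        assert mine[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-6)
        assert mine[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-6)


def test_blocked_reaction_has_zero_range(aromatic_toy):
    m = aromatic_toy.model.copy()
    m.reactions["PKS"].upper_bound = 0.0
    ranges = lp.fva(m, reactions=["PKS", "PRODt", "EX_prod_e"])
    for rid in ("PKS", "PRODt", "EX_prod_e"):
        assert ranges[rid] == pytest.approx((0.0, 0.0), abs=1e-9)


def test_optimal_fluxes_lie_within_fva_ranges(demo_mr):
    res = lp.fba(demo_mr, objective="BIOMASS")
    ranges = lp.fva(demo_mr, fix_objective_fraction=1.0, objective="BIOMASS")
    for rid, v in res.fluxes.items():
        lo, hi = ranges[rid]
        assert lo - 1e-6 <= v <= hi + 1e-6


def test_fva_infeasible_region_raises():
    m = chain_model()
    with pytest.raises(lp.InfeasibleRegionError):
        lp.fva(m, constraints=[({"SINK": 1.0}, ">=", 11.0)])


# -- production envelopes ----------------------------------------------------

def test_envelope_endpoints_match_fva(demo_mr):
    env = lp.production_envelope(demo_mr, "MRt1", "BIOMASS", n_points=15)
    x_range = lp.fva(demo_mr, reactions=["MRt1"])["MRt1"]
    assert env.x[0] == pytest.approx(x_range[0], abs=1e-6)
    assert env.x[-1] == pytest.approx(x_range[1], abs=1e-6)


def test_envelope_concavity_and_dense_scan_agreement(demo_mr):
    coarse = lp.production_envelope(demo_mr, "MRt1", "BIOMASS", n_points=20)
    dense = lp.production_envelope(demo_mr, "MRt1", "BIOMASS", n_points=200)
    up = np.interp(coarse.x, dense.x, dense.y_max)
    lo = np.interp(coarse.x, dense.x, dense.y_min)
    assert np.allclose(coarse.y_max, up, atol=1e-3)
    assert np.allclose(coarse.y_min, lo, atol=1e-3)
    # piecewise-linear LP parametrics: upper concave, lower convex
    d2_up = np.diff(dense.y_max, 2)
    d2_lo = np.diff(dense.y_min, 2)
    assert (d2_up <= 1e-5).all()
    assert (d2_lo >= -1e-5).all()


def test_envelope_blocked_x_gives_single_point(aromatic_toy):
    m = apply_reaction_knockouts(aromatic_toy.model, {"PKS"})
    with pytest.warns(UserWarning, match="blocked"):
        env = lp.production_envelope(m, "EX_prod_e", "BIOMASS")
    assert len(env.x) == 1


def test_envelope_requires_two_points(demo_mr):
    with pytest.raises(ValueError):
        lp.production_envelope(demo_mr, "MRt1", "BIOMASS", n_points=1)


# -- flux-sum ----------------------------------------------------------------

def test_flux_sum_simple_two_reaction_case():
    m = MetabolicModel(
        "fs",
        metabolites=[Metabolite("x_c")],
        reactions=[
            Reaction("IN", {"x_c": 1}, 0, 10),
            Reaction("OUT", {"x_c": -1}, 0, 10),
        ],
        objective_reaction="OUT",
    )
    report = lp.flux_sum(m, {"IN": 2.0, "OUT": 2.0}, metabolites=["x_c"])
    assert report["x_c"] == pytest.approx(2.0)
    assert report.producing["x_c"] == [("IN", 2.0)]
    assert report.consuming["x_c"] == [("OUT", 2.0)]


def test_flux_sum_conservation_at_optimum(demo_mr):
    res = lp.fba(demo_mr, objective="BIOMASS", tie_break=True)
    report = lp.flux_sum(demo_mr, res)
    for met in demo_mr.metabolites:
        prod = sum(r for _, r in report.producing[met])
        cons = sum(r for _, r in report.consuming[met])
        assert prod == pytest.approx(cons, abs=1e-6)
        assert report[met] == pytest.approx(prod, abs=1e-6)


def test_atp_flux_sum_depends_on_objective(aromatic_toy):
    """Hand-derived turnover: under growth the respiration flux is
    e*b + m0 = 2*(19/5) + 1 = 8.6; under max product it is (yp - c)*U = 10."""
    model = aromatic_toy.model
    growth = lp.fba(model, objective="BIOMASS", tie_break=True)
    product = lp.fba(model, objective="EX_prod_e", tie_break=True)
    phi_growth = lp.flux_sum(model, growth, ["atp_c"])["atp_c"]
    phi_product = lp.flux_sum(model, product, ["atp_c"])["atp_c"]
    assert phi_growth == pytest.approx(8.6, abs=1e-6)
    assert phi_product == pytest.approx(10.0, abs=1e-6)


def test_flux_sum_unknown_metabolite_raises(demo_mr):
    res = lp.fba(demo_mr, objective="BIOMASS")
    with pytest.raises(KeyError):
        lp.flux_sum(demo_mr, res, metabolites=["nope_c"])


# -- blocked / essential -----------------------------------------------------

def test_find_blocked_cases(aromatic_toy):
    m = aromatic_toy.model.copy()
    m.reactions["NS2"].lower_bound = 0.0
    m.reactions["NS2"].upper_bound = 0.0
    blocked = lp.find_blocked(m)
    assert "NS2" in blocked


def test_find_blocked_matches_cobra(demo_glc, tmp_path):
    from cobra.flux_analysis import find_blocked_reactions

    cm = to_cobra(demo_glc, tmp_path)
    cm.objective = "BIOMASS"
    theirs = set(find_blocked_reactions(cm))
    mine = lp.find_blocked(demo_glc)
    assert mine == theirs


def test_find_essential_matches_brute_force(aromatic_toy, tmp_path):
    """Independent oracle: single knockouts simulated in cobrapy."""
    model = aromatic_toy.model
    cm = to_cobra(model, tmp_path)
    cm.objective = "BIOMASS"
    expected = set()
    for rxn in cm.reactions:
        with cm:
            rxn.knock_out()
            growth = cm.slim_optimize(error_value=0.0)
            if growth is None or abs(growth) < 1e-6 or np.isnan(growth):
                expected.add(rxn.id)
    assert lp.find_essential(model, kind="reactions") == expected
    assert "BIOMASS" in expected


def test_gene_essentiality(aromatic_toy):
    genes = lp.find_essential(aromatic_toy.model, kind="genes")
    assert "gCATA" in genes and "gRESP" in genes
    # isoenzymes individually dispensable
    assert "gNS1a" not in genes and "gNS1b" not in genes
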