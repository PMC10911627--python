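"""Model data structures, SBML round trips, and editing operations."""

import random

import pytest

from azodesign import lp
from azodesign.model import (
    DEFAULT_BOUND,
    MediumSpec,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    SBMLReadError,
    add_reactions,
    apply_dye_pathway_extension,
    apply_gene_knockouts,
    apply_medium,
    apply_reaction_knockouts,
    mr_transport_reactions,
    parse_equation,
    read_reaction_table,
    read_sbml,
    write_sbml,
)
from azodesign.synthetic import make_demo_model


# -- SBML round trips --------------------------------------------------------

def test_sbml_roundtrip_is_identity(aromatic_toy, tmp_path):
    path = tmp_path / "toy.xml"
    write_sbml(aromatic_toy.model, path)
    again = read_sbml(path)
    assert again.equivalent(aromatic_toy.model)


def test_gpr_survives_sbml_roundtrip(tmp_path):
    m = MetabolicModel(
        "g",
        metabolites=[Metabolite("a_c"), Metabolite("b_e", compartment="e")],
        reactions=[
            Reaction("R1", {"a_c": -1, "b_e": 1}, 0, 10, gpr="(a and b) or c"),
            Reaction("EX_b_e", {"b_e": -1}, 0, 10),
        ],
        objective_reaction="R1",
    )
    write_sbml(m, tmp_path / "m.xml")
    again = read_sbml(tmp_path / "m.xml")
    rule = again.reactions["R1"].gpr
    assert rule.genes() == {"a", "b", "c"}
    assert rule.evaluate({"a"}) is True
    assert rule.evaluate({"a", "c"}) is False


def test_empty_model_roundtrip(tmp_path):
    m = MetabolicModel("empty")
    write_sbml(m, tmp_path / "e.xml")
    assert len(read_sbml(tmp_path / "e.xml").reactions) == 0


def test_malformed_sbml_raises(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("<sbml><model><unclosed></model>")
    with pytest.raises(SBMLReadError):
        read_sbml(bad)


def test_undeclared_metabolite_is_named_in_error():
    m = MetabolicModel("m", metabolites=[Metabolite("a_c")])
    with pytest.raises(ModelValidationError, match="ghost_c"):
        m.add_reaction(Reaction("R", {"a_c": -1, "ghost_c": 1}))


# -- knockouts ---------------------------------------------------------------

def test_empty_gene_knockout_leaves_model_unchanged(aromatic_toy):
    out = apply_gene_knockouts(aromatic_toy.model, set())
    assert out.equivalent(aromatic_toy.model)


def test_gene_knockouts_are_pure_and_respect_or_logic(aromatic_toy):
    model = aromatic_toy.model
    before = model.content_key()
    # NS1 is catalyzed by isoenzymes gNS1a|gNS1b: one knockout keeps it open
    out = apply_gene_knockouts(model, {"gNS1a"})
    assert out.reactions["NS1"].upper_bound > 0
    both = apply_gene_knockouts(model, {"gNS1a", "gNS1b"})
    assert both.reactions["NS1"].upper_bound == both.reactions["NS1"].lower_bound == 0
    # PKS needs both subunits: one gene kills it
    sub = apply_gene_knockouts(model, {"gPKSa"})
    assert sub.reactions["PKS"].upper_bound == 0
    assert model.content_key() == before


def test_unknown_ids_raise(aromatic_toy):
    with pytest.raises(KeyError):
        apply_gene_knockouts(aromatic_toy.model, {"not_a_gene"})
    with pytest.raises(KeyError):
        apply_reaction_knockouts(aromatic_toy.model, {"not_a_reaction"})


def test_knocking_out_objective_zeroes_fba(aromatic_toy):
    ko = apply_reaction_knockouts(aromatic_toy.model, {"BIOMASS"})
    res = lp.fba(ko, objective="BIOMASS")
    assert res.optimal and abs(res.objective_value) < 1e-9


def test_knockout_of_blocked_reaction_keeps_optimum():
    base = make_demo_model(include_dye_pathway=False)
    from azodesign.synthetic import demo_medium

    glc = apply_medium(base, demo_medium("glc"))
    # catechol dioxygenase is blocked in the base model (no catechol source)
    assert "CATDO" in lp.find_blocked(glc)
    before = lp.fba(glc, objective="BIOMASS").objective_value
    after = lp.fba(
        apply_reaction_knockouts(glc, {"CATDO"}), objective="BIOMASS"
    ).objective_value
    assert after == pytest.approx(before, abs=1e-9)


def test_knockout_monotonicity(aromatic_toy):
    """A superset of knockouts never increases the FBA optimum."""
    model = aromatic_toy.model
    rng = random.Random(7)
    knockable = [r for r in model.reactions if r not in ("BIOMASS", "ATPM")]
    for _ in range(25):
        small = set(rng.sample(knockable, rng.randint(0, 2)))
        big = small | set(rng.sample(knockable, rng.randint(1, 2)))
        f_small = lp.fba(apply_reaction_knockouts(model, small), objective="BIOMASS")
        f_big = lp.fba(apply_reaction_knockouts(model, big), objective="BIOMASS")
        v_small = f_small.objective_value if f_small.optimal else 0.0
        v_big = f_big.objective_value if f_big.optimal else 0.0
        assert v_big <= v_small + 1e-8


# -- media -------------------------------------------------------------------

def test_medium_sign_convention(demo_model):
    from azodesign.synthetic import demo_medium

    m = apply_medium(demo_model, demo_medium("mr"))
    assert m.reactions["EX_mr_e"].lower_bound == -1000.0
    assert m.reactions["EX_o2_e"].lower_bound == -30.0
    # glucose exchange absent from the MR medium: closed for uptake only
    assert m.reactions["EX_glc__D_e"].lower_bound == 0.0
    assert m.reactions["EX_glc__D_e"].upper_bound > 0


def test_empty_medium_closes_all_uptake(demo_model):
    closed = apply_medium(demo_model, MediumSpec({}))
    res = lp.fba(closed, objective="BIOMASS")
    # nothing can enter, and maintenance ATP cannot be met
    assert res.status == "infeasible" or abs(res.objective_value) < 1e-9


def test_medium_rejects_non_exchange_keys(demo_model):
    with pytest.raises(KeyError):
        apply_medium(demo_model, MediumSpec({"TCA": 5.0}))
    with pytest.raises(ValueError):
        MediumSpec({"EX_o2_e": -3.0})


def test_glc_mr_medium_opens_both(demo_model):
    from azodesign.synthetic import demo_medium

    m = apply_medium(demo_model, demo_medium("glc_mr"))
    assert m.reactions["EX_mr_e"].lower_bound == -1000.0
    assert m.reactions["EX_glc__D_e"].lower_bound == -10.0


# -- pathway extension and reaction tables -----------------------------------

def test_azoreductase_consumes_two_nadh_per_dye():
    azor = {r.id: r for r in mr_transport_reactions()}["AzoR_MR"]
    assert azor.stoichiometry["nadh_c"] == -2.0
    assert azor.stoichiometry["mr_c"] == -1.0
    assert azor.stoichiometry["anth_c"] == 1.0
    assert azor.stoichiometry["nad_c"] == 2.0


def test_extension_is_duplicate_safe():
    base = make_demo_model(include_dye_pathway=False)
    extended = apply_dye_pathway_extension(base)
    with pytest.raises(ModelValidationError, match="already present"):
        apply_dye_pathway_extension(extended)
    # explicit opt-out tolerates re-application
    again = apply_dye_pathway_extension(extended, on_duplicate="skip")
    assert again.equivalent(extended)


def test_extension_enables_act_on_dye():
    from azodesign.synthetic import demo_medium

    base = make_demo_model(include_dye_pathway=False)
    extended = apply_dye_pathway_extension(base)
    mr = apply_medium(extended, demo_medium("mr"))
    res = lp.fba(mr, objective="ACTt")
    assert res.optimal and res.objective_value > 1e-6


def test_parse_equation_and_table(tmp_path):
    stoich = parse_equation("mr[c] + 2 h[c] + 2.0 nadh[c] --> dmppd[c] + anth[c]")
    assert stoich == {
        "mr_c": -1.0, "h_c": -2.0, "nadh_c": -2.0, "dmppd_c": 1.0, "anth_c": 1.0
    }
    assert parse_equation("a[e] -->") == {"a_e": -1.0}
    assert parse_equation("a[c] <-- b[c]") == {"b_c": -1.0, "a_c": 1.0}
    with pytest.raises(ValueError):
        parse_equation("a[c] + b[c]")  # no arrow
    with pytest.raises(ValueError):
        parse_equation("a --> b[c]")  # missing compartment suffix

    table = tmp_path / "rxns.tsv"
    table.write_text("# comment\nR1\ta[c] <=> b[c]\t\t\tg1 or g2\n")
    (rxn,) = read_reaction_table(table)
    assert rxn.lower_bound == -DEFAULT_BOUND and rxn.upper_bound == DEFAULT_BOUND
    assert rxn.gpr.genes() == {"g1", "g2"}


def test_add_reactions_creates_new_metabolites(aromatic_toy):
    new = Reaction("NEW", {"brandnew_c": -1, "prod_c": 1}, 0, 5)
    out = add_reactions(aromatic_toy.model, [new])
    assert "brandnew_c" in out.metabolites
    assert out.metabolites["brandnew_c"].compartment == "c"
    assert "brandnew_c" not in aromatic_toy.model.metabolites
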