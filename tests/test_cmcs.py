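"""Constrained minimal cut sets: preprocessing, MILP enumeration vs the
exhaustive oracle, verification, and the threshold sweep."""

import pytest

from azodesign import cmcs, lp
from azodesign.model import apply_reaction_knockouts
from azodesign.synthetic import make_toy_model, sample_toy_spec


@pytest.fixture(scope="module")
def toy_regions(aromatic_toy):
    target, desired = cmcs.build_regions(
        aromatic_toy.model, "EX_prod_e", "BIOMASS", 0, 0
    )
    return target, desired


# -- preprocessing -----------------------------------------------------------

def test_preprocessing_matches_manual_category_audit(aromatic_toy):
    """Hand classification of the toy's 14 reactions: exchanges and
    transports out, gene-less pseudo-reactions out, the essential substrate
    entry and respiration out — candidates are the NADH sources and the
    product pathway."""
    model = aromatic_toy.model
    candidates = cmcs.preprocess_targets(model)
    assert candidates == {"NS1", "NS2", "PKS"}
    # spot checks per category
    assert "EX_suba_e" not in candidates  # boundary
    assert "SUBAt1" not in candidates  # transport
    assert "ATPM" not in candidates and "BIOMASS" not in candidates  # no GPR
    assert "CATA" not in candidates and "RESP" not in candidates  # essential


def test_peripheral_reactions_are_excluded(aromatic_toy):
    model = aromatic_toy.model.copy()
    model.peripheral_reactions = {"PKS"}
    assert "PKS" not in cmcs.preprocess_targets(model)


# -- verification ------------------------------------------------------------

def test_empty_cut_set_does_not_block_feasible_target(aromatic_toy, toy_regions):
    target, desired = toy_regions
    flags = cmcs.verify_cut_set(aromatic_toy.model, set(), target, desired)
    assert flags["target_blocked"] is False


def test_planted_set_verifies_and_superset_is_not_minimal(aromatic_toy, toy_regions):
    target, desired = toy_regions
    planted = set(aromatic_toy.planted_cutset)
    flags = cmcs.verify_cut_set(aromatic_toy.model, planted, target, desired)
    assert flags == {
        "target_blocked": True, "desired_feasible": True, "minimal": True
    }
    superset = planted | {"PKS"}
    flags = cmcs.verify_cut_set(aromatic_toy.model, superset, target, desired)
    assert flags["minimal"] is False


# -- enumeration -------------------------------------------------------------

def test_enumeration_on_already_blocked_target(aromatic_toy, toy_regions):
    target, desired = toy_regions
    pre_knocked = apply_reaction_knockouts(
        aromatic_toy.model, aromatic_toy.planted_cutset
    )
    result = cmcs.enumerate_mcs(pre_knocked, {"PKS"}, target, desired)
    assert len(result) == 1 and result[0].reactions == frozenset()


def test_enumeration_recovers_planted_set(aromatic_toy, toy_regions):
    target, desired = toy_regions
    candidates = cmcs.preprocess_targets(aromatic_toy.model)
    found = cmcs.enumerate_mcs(
        aromatic_toy.model, candidates, target, desired,
        max_size=4, time_limit_s=60,
    )
    assert {cs.reactions for cs in found} == {aromatic_toy.planted_cutset}
    for cs in found:  # soundness flags recorded on every returned set
        assert cs.verified["target_blocked"] and cs.verified["desired_feasible"]
        assert cs.verified["minimal"]


@pytest.mark.parametrize("mode", ["aromatic", "sugar"])
@pytest.mark.parametrize("seed", range(10))
def test_milp_equals_exhaustive_oracle_on_randomized_toys(mode, seed):
    """Completeness/soundness at desk scale: 20 randomized instances, MILP
    enumeration equals brute-force subset search."""
    bundle = make_toy_model(sample_toy_spec(mode, seed))
    model = bundle.model
    target, desired = cmcs.build_regions(model, "EX_prod_e", "BIOMASS", 0, 0)
    candidates = cmcs.preprocess_targets(model)
    assert len(candidates) <= 12
    max_size = len(bundle.planted_cutset) + 2 if bundle.planted_cutset else 4
    milp_sets = {
        cs.reactions
        for cs in cmcs.enumerate_mcs(
            model, candidates, target, desired,
            max_size=max_size, time_limit_s=120, max_solutions=50,
        )
    }
    oracle_sets = {
        cs.reactions
        for cs in cmcs.exhaustive_mcs(model, candidates, target, desired,
                                      max_size=max_size)
    }
    assert milp_sets == oracle_sets
    if mode == "sugar":
        assert milp_sets == set()
    else:
        assert milp_sets == {bundle.planted_cutset}


def test_unknown_candidates_raise(aromatic_toy, toy_regions):
    target, desired = toy_regions
    with pytest.raises(KeyError):
        cmcs.enumerate_mcs(aromatic_toy.model, {"nope"}, target, desired)


# -- threshold sweep ---------------------------------------------------------

def test_sweep_order_is_relaxed_to_strict(aromatic_toy):
    sweep = cmcs.threshold_sweep(
        aromatic_toy.model, "EX_prod_e", "BIOMASS", thresholds=(1, 0),
        max_size=3, time_limit_s=60,
    )
    coords = [(c["min_biomass_pct"], c["min_act_pct"]) for c in sweep.grid]
    assert coords == [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]


def test_sweep_dichotomy_and_planted_recovery(aromatic_toy, sugar_toy):
    kwargs = dict(thresholds=(0, 1, 5), max_size=4, time_limit_s=60)
    arom = cmcs.threshold_sweep(
        aromatic_toy.model, "EX_prod_e", "BIOMASS", **kwargs
    )
    arom_sets = {cs.reactions for cell in arom.grid for cs in cell["cut_sets"]}
    assert arom_sets == {aromatic_toy.planted_cutset}
    # the planted set appears at the (1%, 1%) grid point specifically
    cell_11 = next(
        c for c in arom.grid
        if (c["min_biomass_pct"], c["min_act_pct"]) == (1.0, 1.0)
    )
    assert {cs.reactions for cs in cell_11["cut_sets"]} == {aromatic_toy.planted_cutset}

    sugar = cmcs.threshold_sweep(sugar_toy.model, "EX_prod_e", "BIOMASS", **kwargs)
    assert sugar.total_solutions() == 0


def test_threshold_monotonicity(aromatic_toy):
    """Any cut set found at a strict threshold pair verifies at looser ones."""
    model = aromatic_toy.model
    strict_t, strict_d = cmcs.build_regions(model, "EX_prod_e", "BIOMASS", 10, 10)
    loose_t, loose_d = cmcs.build_regions(model, "EX_prod_e", "BIOMASS", 0, 0)
    candidates = cmcs.preprocess_targets(model)
    strict_sets = cmcs.enumerate_mcs(
        model, candidates, strict_t, strict_d, max_size=4, time_limit_s=60
    )
    for cs in strict_sets:
        flags = cmcs.verify_cut_set(model, cs.reactions, loose_t, loose_d)
        assert flags["target_blocked"] and flags["desired_feasible"]


def test_sweep_rejects_bad_percentages(aromatic_toy):
    with pytest.raises(ValueError):
        cmcs.threshold_sweep(
            aromatic_toy.model, "EX_prod_e", "BIOMASS", thresholds=(0, 120)
        )


def test_zero_threshold_is_strict_positivity(aromatic_toy):
    """A 0% threshold resolves to a small positive fraction of the optimum,
    not literally zero (the degenerate region would be meaningless)."""
    target, desired = cmcs.build_regions(
        aromatic_toy.model, "EX_prod_e", "BIOMASS", 0, 0
    )
    (rid, sense, rhs), = target.constraints
    assert rid == "EX_prod_e" and sense == "<=" and 0 < rhs < 1e-3
    (rid, sense, rhs), = desired.constraints
    assert rid == "BIOMASS" and sense == ">=" and 0 < rhs < 1e-3
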