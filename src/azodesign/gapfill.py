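"""FBA-driven gap filling.

Finds the smallest subset of candidate reactions whose addition makes a
target objective (e.g. product export) carry flux. The search is exhaustive
by cardinality — single additions first, then pairs, and so on — which
mirrors the manual design loop it automates and keeps the result independent
of any MILP heuristics. Ties are broken by candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from . import lp
from .model import MetabolicModel, Reaction, add_reactions

FEASIBILITY_THRESHOLD = 1e-6


@dataclass
class GapfillResult:
    added_reactions: list[str]
    feasible: bool
    objective_value_after: float | None = None


def _objective_optimum(model: MetabolicModel, objective: str) -> float:
    res = lp.fba(model, objective=objective)
    return res.objective_value if res.optimal else 0.0


def gapfill(
    model: MetabolicModel,
    universal: Sequence[Reaction],
    objective: str,
    max_additions: int = 2,
    threshold: float = FEASIBILITY_THRESHOLD,
) -> GapfillResult:
    """Minimum-cardinality candidate subset making ``objective`` feasible.

    Candidate reactions may reference metabolites absent from the model; they
    are created on the fly with compartments parsed from their id suffixes.
    Returns ``feasible=False`` (not an exception) when no subset of size up to
    ``max_additions`` works. An already-feasible model yields an empty set.
    """
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    base_opt = _objective_optimum(model, objective)
    if base_opt > threshold:
        return GapfillResult([], True, base_opt)

    by_id = {}
    for rxn in universal:
        if rxn.id in by_id:
            raise ValueError(f"duplicate candidate reaction id {rxn.id!r}")
        by_id[rxn.id] = rxn
    order = list(by_id)

    for size in range(1, max_additions + 1):
        for combo in combinations(order, size):
            trial = add_reactions(
                model, [by_id[r] for r in combo], on_duplicate="error"
            )
            opt = _objective_optimum(trial, objective)
            if opt > threshold:
                return GapfillResult(list(combo), True, opt)
    return GapfillResult([], False, None)


@dataclass
class RouteComparison:
    """FBA flux through an alternative route vs the main reaction."""

    route_fluxes: dict[str, float] = field(default_factory=dict)
    main_flux: float = 0.0
    route_total: float = 0.0

    @property
    def main_dominates(self) -> bool:
        return abs(self.main_flux) >= self.route_total


def check_alternative_route(
    model: MetabolicModel,
    route_reactions: Sequence[str],
    main_reaction: str,
    objective: str | None = None,
) -> RouteComparison:
    """Compare flux carried by an alternative route against the main reaction
    under a (parsimonious) FBA optimum for the given objective."""
    for rid in list(route_reactions) + [main_reaction]:
        if rid not in model.reactions:
            raise KeyError(f"reaction {rid!r} not in model")
    res = lp.fba(model, objective=objective, tie_break=True)
    if not res.optimal:
        return RouteComparison({}, 0.0, 0.0)
    route = {rid: res.fluxes[rid] for rid in route_reactions}
    return RouteComparison(
        route_fluxes=route,
        main_flux=res.fluxes[main_reaction],
        route_total=sum(abs(v) for v in route.values()),
    )
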