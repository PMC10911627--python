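"""Linear-programming core: FBA, FVA, production envelopes, flux-sums.

All solves go through scipy's HiGHS interface. Flux balance analysis (FBA)
maximizes or minimizes one reaction flux subject to steady state S v = 0 and
flux bounds; flux variability analysis (FVA) reports the attainable interval
of each flux; production envelopes trace the (x, y) flux region by fixing one
flux on a grid and optimizing the other; the flux-sum of a metabolite,

    Phi_i = 0.5 * sum_j |S_ij v_j|,

is its total turnover (production = consumption at steady state).

Degenerate optima: the objective value of an LP is unique but the optimal
flux vector generally is not. Whenever a single representative vector is
needed (flux-sums, pathway utilization) a parsimonious tie-break is applied:
minimize sum_j |v_j| subject to the objective being held at its optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, apply_gene_knockouts, apply_reaction_knockouts

FEASIBILITY_TOL = 1e-9
BLOCKED_EPS = 1e-9
GROWTH_FLOOR = 1e-6

#: A linear constraint over reaction fluxes: (coefficients, sense, rhs).
Constraint = tuple[Mapping[str, float], str, float]


class SolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


class InfeasibleRegionError(RuntimeError):
    """The constrained flux region is empty."""

    def __init__(self, message: str, n_constraints: int = 0) -> None:
        super().__init__(message)
        self.n_constraints = n_constraints


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_reaction: str | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """Per-reaction feasible flux interval (min_flux, max_flux)."""

    ranges: dict[str, tuple[float, float]]

    def minimum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][0]

    def maximum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][1]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def __iter__(self):
        return iter(self.ranges)


@dataclass
class Envelope:
    """Production envelope: y-range of one flux along a grid of another."""

    x_reaction: str
    y_reaction: str
    x: list[float]
    y_min: list[float]
    y_max: list[float]

    def as_rows(self) -> list[tuple[float, float, float]]:
        return list(zip(self.x, self.y_min, self.y_max))


@dataclass
class FluxSumReport:
    """Flux-sum per metabolite plus signed producer/consumer contributions."""

    flux_sums: dict[str, float]
    producing: dict[str, list[tuple[str, float]]]
    consuming: dict[str, list[tuple[str, float]]]

    def __getitem__(self, met_id: str) -> float:
        return self.flux_sums[met_id]


# ---------------------------------------------------------------------------
# low-level solve helpers
# ---------------------------------------------------------------------------

def _arrays(model: MetabolicModel):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids], dtype=float)
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids], dtype=float)
    return S.tocsr(), lb, ub, rxn_ids


def _constraint_rows(
    constraints: Sequence[Constraint], rxn_index: Mapping[str, int], n: int
):
    """Split user constraints into (A_ub, b_ub, A_eq_extra, b_eq_extra)."""
    ub_rows, ub_rhs, eq_rows, eq_rhs = [], [], [], []
    for coefs, sense, rhs in constraints:
        row = np.zeros(n)
        for rid, coef in coefs.items():
            row[rxn_index[rid]] = coef
        if sense == "<=":
            ub_rows.append(row)
            ub_rhs.append(rhs)
        elif sense == ">=":
            ub_rows.append(-row)
            ub_rhs.append(-rhs)
        elif sense == "==":
            eq_rows.append(row)
            eq_rhs.append(rhs)
        else:
            raise ValueError(f"unknown constraint sense {sense!r}")
    return ub_rows, ub_rhs, eq_rows, eq_rhs


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def _linprog(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status in ("error", "iteration_limit"):
        raise SolverError(f"LP backend failure: {res.message}")
    return status, res


def _solve_model(
    model: MetabolicModel,
    c: np.ndarray,
    constraints: Sequence[Constraint] = (),
    arrays=None,
):
    S, lb, ub, rxn_ids = arrays if arrays is not None else _arrays(model)
    n = len(rxn_ids)
    rxn_index = {r: i for i, r in enumerate(rxn_ids)}
    ub_rows, ub_rhs, eq_rows, eq_rhs = _constraint_rows(constraints, rxn_index, n)
    A_eq = sparse.vstack([S] + [sparse.csr_matrix(r) for r in eq_rows]) if eq_rows else S
    b_eq = np.concatenate([np.zeros(S.shape[0]), np.asarray(eq_rhs)]) if eq_rows else np.zeros(S.shape[0])
    A_ub = np.vstack(ub_rows) if ub_rows else None
    b_ub = np.asarray(ub_rhs) if ub_rows else None
    status, res = _linprog(c, A_ub, b_ub, A_eq, b_eq, np.column_stack([lb, ub]))
    return status, res, rxn_ids


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def fba(
    model: MetabolicModel,
    objective: str | None = None,
    direction: str = "max",
    constraints: Sequence[Constraint] = (),
    tie_break: bool = False,
) -> FBAResult:
    """Flux balance analysis: optimize one reaction flux at steady state.

    With ``tie_break=True`` the reported flux vector is the parsimonious one
    (minimal total absolute flux at the optimal objective value); the
    objective value itself is vertex-independent either way.
    """
    objective = objective or model.objective_reaction
    if objective is None:
        raise ValueError("no objective reaction given and model declares none")
    if objective not in model.reactions:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")

    arrays = _arrays(model)
    S, lb, ub, rxn_ids = arrays
    n = len(rxn_ids)
    j = rxn_ids.index(objective)
    sign = -1.0 if direction == "max" else 1.0
    c = np.zeros(n)
    c[j] = sign

    status, res, _ = _solve_model(model, c, constraints, arrays)
    if status != "optimal":
        return FBAResult(status, None, {}, objective)
    opt = float(res.x[j])
    fluxes = dict(zip(rxn_ids, map(float, res.x)))

    if tie_break:
        fluxes = _parsimonious_vector(arrays, j, opt, constraints)
    return FBAResult("optimal", opt, fluxes, objective)


def _parsimonious_vector(
    arrays, obj_index: int, opt: float, constraints: Sequence[Constraint]
) -> dict[str, float]:
    """Minimize sum|v| at the fixed objective value (split-variable LP)."""
    S, lb, ub, rxn_ids = arrays
    n = len(rxn_ids)
    rxn_index = {r: i for i, r in enumerate(rxn_ids)}
    # v = p - q with p, q >= 0
    p_lo, p_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    q_lo, q_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    bounds = np.column_stack(
        [np.concatenate([p_lo, q_lo]), np.concatenate([p_hi, q_hi])]
    )
    S2 = sparse.hstack([S, -S]).tocsr()
    obj_row = np.zeros(2 * n)
    obj_row[obj_index] = 1.0
    obj_row[n + obj_index] = -1.0
    ub_rows, ub_rhs, eq_rows, eq_rhs = _constraint_rows(constraints, rxn_index, n)
    eq_stack = [S2, sparse.csr_matrix(obj_row)]
    b_eq = [np.zeros(S.shape[0]), [opt]]
    for row, rhs in zip(eq_rows, eq_rhs):
        eq_stack.append(sparse.csr_matrix(np.concatenate([row, -row])))
        b_eq.append([rhs])
    A_ub = (
        np.vstack([np.concatenate([r, -r]) for r in ub_rows]) if ub_rows else None
    )
    b_ub = np.asarray(ub_rhs) if ub_rows else None
    c = np.ones(2 * n)
    status, res = _linprog(
        c, A_ub, b_ub, sparse.vstack(eq_stack), np.concatenate(b_eq), bounds
    )
    if status != "optimal":  # pragma: no cover - fixed-optimum LP is feasible
        raise SolverError(f"parsimonious tie-break LP returned {status}")
    v = res.x[:n] - res.x[n:]
    return dict(zip(rxn_ids, map(float, v)))


# ---------------------------------------------------------------------------
# FVA and derived analyses
# ---------------------------------------------------------------------------

def fva(
    model: MetabolicModel,
    reactions: Iterable[str] | None = None,
    fix_objective_fraction: float | None = None,
    objective: str | None = None,
    constraints: Sequence[Constraint] = (),
) -> FluxRange:
    """Min and max flux of each reaction over the (optionally growth-constrained)
    feasible region; two LPs per reaction."""
    targets = list(reactions) if reactions is not None else list(model.reactions)
    unknown = set(targets) - set(model.reactions)
    if unknown:
        raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
    constraints = list(constraints)
    if fix_objective_fraction is not None:
        if not 0.0 <= fix_objective_fraction <= 1.0:
            raise ValueError("fix_objective_fraction must lie in [0, 1]")
        objective = objective or model.objective_reaction
        ref = fba(model, objective=objective, constraints=constraints)
        if not ref.optimal:
            raise InfeasibleRegionError(
                f"reference FBA is {ref.status}; cannot fix objective fraction",
                n_constraints=len(constraints),
            )
        constraints.append(
            ({objective: 1.0}, ">=", fix_objective_fraction * ref.objective_value)
        )

    arrays = _arrays(model)
    S, lb, ub, rxn_ids = arrays
    n = len(rxn_ids)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        lohi = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            status, res, _ = _solve_model(model, c, constraints, arrays)
            if status == "infeasible":
                raise InfeasibleRegionError(
                    f"flux region is infeasible ({len(constraints)} extra constraints)",
                    n_constraints=len(constraints),
                )
            if status == "unbounded":
                lohi.append(-np.inf if sign > 0 else np.inf)
            else:
                lohi.append(float(res.x[j]))
        ranges[rid] = (lohi[0], lohi[1])
    return FluxRange(ranges)


def production_envelope(
    model: MetabolicModel,
    x_reaction: str,
    y_reaction: str,
    n_points: int = 40,
) -> Envelope:
    """Trace y_min/y_max of ``y_reaction`` over a grid spanning the feasible
    range of ``x_reaction`` (two LPs per grid point)."""
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    for rid in (x_reaction, y_reaction):
        if rid not in model.reactions:
            raise KeyError(f"reaction {rid!r} not in model")
    x_range = fva(model, reactions=[x_reaction])[x_reaction]
    x_lo, x_hi = x_range
    if abs(x_hi - x_lo) < 1e-9:
        warnings.warn(
            f"{x_reaction} is blocked or fixed; returning single-point envelope",
            stacklevel=2,
        )
        y = fva(model, reactions=[y_reaction])[y_reaction]
        return Envelope(x_reaction, y_reaction, [x_lo], [y[0]], [y[1]])

    arrays = _arrays(model)
    S, lb, ub, rxn_ids = arrays
    n = len(rxn_ids)
    jx, jy = rxn_ids.index(x_reaction), rxn_ids.index(y_reaction)
    grid = np.linspace(x_lo, x_hi, n_points)
    xs, ymins, ymaxs = [], [], []
    for x in grid:
        lb2, ub2 = lb.copy(), ub.copy()
        lb2[jx] = ub2[jx] = x
        vals = []
        ok = True
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[jy] = sign
            status, res = _linprog(
                c, None, None, S, np.zeros(S.shape[0]), np.column_stack([lb2, ub2])
            )
            if status != "optimal":
                # endpoints can be marginally infeasible in floating point:
                # relax the fixed x by a hair towards the interior
                nudge = 1e-7 * max(1.0, abs(x))
                shift = nudge if x < (x_lo + x_hi) / 2 else -nudge
                lb2[jx] = ub2[jx] = x + shift
                status, res = _linprog(
                    c, None, None, S, np.zeros(S.shape[0]), np.column_stack([lb2, ub2])
                )
            if status != "optimal":
                ok = False
                break
            vals.append(float(res.x[jy]))
        if ok:
            xs.append(float(x))
            ymins.append(vals[0])
            ymaxs.append(vals[1])
    return Envelope(x_reaction, y_reaction, xs, ymins, ymaxs)


def flux_sum(
    model: MetabolicModel,
    fluxes: FBAResult | Mapping[str, float],
    metabolites: Iterable[str] | None = None,
) -> FluxSumReport:
    """Flux-sum Phi_i = 0.5 sum_j |S_ij v_j| for each requested metabolite,
    with the producing and consuming contributions listed separately."""
    if isinstance(fluxes, FBAResult):
        if not fluxes.optimal:
            raise ValueError("flux_sum requires an optimal FBA result")
        vec = fluxes.fluxes
    else:
        vec = dict(fluxes)
    mets = list(metabolites) if metabolites is not None else list(model.metabolites)
    unknown = set(mets) - set(model.metabolites)
    if unknown:
        raise KeyError(f"unknown metabolite ids: {sorted(unknown)}")

    sums: dict[str, float] = {}
    producing: dict[str, list[tuple[str, float]]] = {}
    consuming: dict[str, list[tuple[str, float]]] = {}
    for met in mets:
        prod, cons = [], []
        for rid, rxn in model.reactions.items():
            coef = rxn.stoichiometry.get(met)
            if coef is None:
                continue
            rate = coef * vec.get(rid, 0.0)
            if rate > FEASIBILITY_TOL:
                prod.append((rid, rate))
            elif rate < -FEASIBILITY_TOL:
                cons.append((rid, -rate))
        total = sum(r for _, r in prod) + sum(r for _, r in cons)
        sums[met] = 0.5 * total
        producing[met] = sorted(prod, key=lambda t: -t[1])
        consuming[met] = sorted(cons, key=lambda t: -t[1])
    return FluxSumReport(sums, producing, consuming)


def find_blocked(
    model: MetabolicModel,
    reactions: Iterable[str] | None = None,
    eps: float = BLOCKED_EPS,
) -> set[str]:
    """Reactions that cannot carry flux anywhere in the feasible region."""
    ranges = fva(model, reactions=reactions)
    return {
        rid
        for rid, (lo, hi) in ranges.ranges.items()
        if abs(lo) <= eps and abs(hi) <= eps
    }


def find_essential(
    model: MetabolicModel,
    kind: str = "reactions",
    growth_floor: float = GROWTH_FLOOR,
    objective: str | None = None,
) -> set[str]:
    """Elements whose single knockout drops the FBA optimum below the floor."""
    objective = objective or model.objective_reaction
    if objective is None:
        raise ValueError("an objective reaction is required")
    if kind not in ("reactions", "genes"):
        raise ValueError("kind must be 'reactions' or 'genes'")
    essential: set[str] = set()
    elements = model.reactions if kind == "reactions" else sorted(model.genes)
    for elem in elements:
        if kind == "reactions":
            ko = apply_reaction_knockouts(model, {elem})
        else:
            ko = apply_gene_knockouts(model, {elem})
        res = fba(ko, objective=objective)
        if (not res.optimal) or res.objective_value < growth_floor:
            essential.add(elem)
    return essential


# ---------------------------------------------------------------------------
# flux-region feasibility (used by the cut-set machinery)
# ---------------------------------------------------------------------------

def region_feasible(
    model: MetabolicModel,
    constraints: Sequence[Constraint],
    knockouts: Iterable[str] = (),
) -> bool:
    """Is the steady-state region non-empty under the extra constraints and
    the given reaction knockouts?"""
    m = apply_reaction_knockouts(model, set(knockouts)) if knockouts else model
    arrays = _arrays(m)
    n = len(arrays[3])
    status, _, _ = _solve_model(m, np.zeros(n), constraints, arrays)
    return status == "optimal"
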