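"""Constrained minimal cut sets (cMCS) for growth-coupled strain design.

A cut set is a set of reaction knockouts that makes an undesired ("target")
flux region infeasible — here, the region where the product flux stays below
a threshold — while a protected ("desired") region, typically growth above a
threshold, remains feasible. Enumerating support-minimal cut sets in order of
increasing size yields candidate strain designs in which the product becomes
an obligatory by-product of metabolism.

Enumeration uses a Farkas-dual MILP: the target region

    S v = 0,  lb <= v <= ub,  T v <= t

is infeasible exactly when a dual certificate (u, p, q, w >= 0) exists with

    S'u + p - q + T'w = 0   and   ub'p - lb'q + t'w <= -1.

Binary knockout indicators z_j relax the dual stationarity row of candidate
reaction j and zero its bound multipliers, encoding lb_j = ub_j = 0. Solutions
are found in nondecreasing cardinality with superset-exclusion cuts; the
desired region is enforced by an LP post-check (every reported set is also
re-verified by independent LPs — soundness is asserted in code, not assumed).

A brute-force oracle (:func:`exhaustive_mcs`) over all candidate subsets is
provided for certification of small instances.
"""

from __future__ import annotations

import contextlib
import os
import sys
import time
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import lp
from .model import MetabolicModel

#: fraction of the reference optimum used for degenerate "0%" thresholds
EPSILON_COUPLING_FRACTION = 1e-6
BIG_M = 1e4

RegionConstraint = tuple[str, str, float]  # (reaction id, "<=" | ">=", rhs)


class MILPBackendError(RuntimeError):
    """The MILP solver failed (distinct from 'no more solutions')."""


def _flush_native_streams() -> None:
    try:
        import ctypes

        ctypes.CDLL(None).fflush(None)
    except Exception:  # pragma: no cover - best effort
        pass


@contextlib.contextmanager
def _quiet_native_stdout():
    """Suppress stray C-level solver chatter on file descriptor 1."""
    try:
        fd = sys.stdout.fileno()
    except (OSError, ValueError):  # e.g. captured stdout without a real fd
        yield
        return
    sys.stdout.flush()
    _flush_native_streams()
    saved = os.dup(fd)
    try:
        with open(os.devnull, "wb") as devnull:
            os.dup2(devnull.fileno(), fd)
        yield
        _flush_native_streams()  # drop buffered chatter while fd is silenced
    finally:
        os.dup2(saved, fd)
        os.close(saved)


class UnsoundCutSetError(RuntimeError):
    """A MILP-reported cut set failed independent LP verification."""


@dataclass
class InterventionRegion:
    """A linear flux-space region (plus implicit steady state and bounds)."""

    kind: str  # "target" (undesired) or "desired" (protected)
    constraints: list[RegionConstraint] = field(default_factory=list)
    threshold_fraction: float | None = None
    reference_objective: str | None = None

    def as_lp_constraints(self) -> list[lp.Constraint]:
        return [({rid: 1.0}, sense, rhs) for rid, sense, rhs in self.constraints]


@dataclass
class CutSet:
    reactions: frozenset[str]
    thresholds: tuple[float, float] | None = None  # (min_biomass_%, min_ACT_%)
    genes: frozenset[str] = frozenset()
    verified: dict[str, bool] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.reactions)

    def to_dict(self) -> dict:
        return {
            "reactions": sorted(self.reactions),
            "size": self.size,
            "thresholds": list(self.thresholds) if self.thresholds else None,
            "genes": sorted(self.genes),
            "verified": dict(self.verified),
        }


@dataclass
class SweepResult:
    """Aggregated cut sets over a (min_biomass_%, min_ACT_%) threshold grid."""

    grid: list[dict] = field(default_factory=list)

    def total_solutions(self) -> int:
        return sum(len(cell["cut_sets"]) for cell in self.grid)

    def to_dict(self) -> dict:
        # wall times stay in memory/logs so serialized sweeps are reproducible
        return {
            "grid": [
                {
                    **{k: v for k, v in cell.items() if k != "wall_time_s"},
                    "cut_sets": [cs.to_dict() for cs in cell["cut_sets"]],
                }
                for cell in self.grid
            ]
        }


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_targets(
    model: MetabolicModel,
    objective: str | None = None,
    growth_floor: float = lp.GROWTH_FLOOR,
) -> set[str]:
    """Knockout candidates: all reactions minus five excluded categories —
    blocked, essential, non-gene-associated, transport/peripheral, boundary.

    Candidates are medium-specific: apply the medium before calling. Blocked
    and essential detection go through the LP engine on the given model.
    """
    objective = objective or model.objective_reaction
    blocked = lp.find_blocked(model)
    essential = lp.find_essential(model, kind="reactions", growth_floor=growth_floor,
                                  objective=objective)
    out = set()
    for rid, rxn in model.reactions.items():
        if rid in blocked or rid in essential:
            continue
        if rxn.gpr.is_empty:
            continue
        if model.is_boundary(rid) or model.is_transport(rid):
            continue
        if rid in model.peripheral_reactions:
            continue
        out.add(rid)
    return out


# ---------------------------------------------------------------------------
# region construction
# ---------------------------------------------------------------------------

def build_regions(
    model: MetabolicModel,
    product_reaction: str,
    biomass_reaction: str,
    min_biomass_pct: float,
    min_product_pct: float,
    reference_model: MetabolicModel | None = None,
    desired_includes_product_floor: bool = False,
) -> tuple[InterventionRegion, InterventionRegion]:
    """Resolve percent-of-optimum thresholds into target/desired regions.

    Percentages refer to FBA optima of the *unmodified* reference model on the
    same medium (defaulting to the given model). A 0% threshold is read as a
    strict-positivity demand at a small fraction of the optimum. The target
    region is "product at or below its threshold"; the desired region is
    "biomass at or above its threshold" (optionally also demanding the product
    floor, behind ``desired_includes_product_floor``).
    """
    ref = reference_model or model
    prod_opt = lp.fba(ref, objective=product_reaction).objective_value
    bio_opt = lp.fba(ref, objective=biomass_reaction).objective_value
    if not prod_opt or not bio_opt:
        raise ValueError(
            "reference model must support positive product and biomass optima"
        )
    prod_thr = max(min_product_pct / 100.0, EPSILON_COUPLING_FRACTION) * prod_opt
    bio_thr = max(min_biomass_pct / 100.0, EPSILON_COUPLING_FRACTION) * bio_opt
    target = InterventionRegion(
        kind="target",
        constraints=[(product_reaction, "<=", prod_thr)],
        threshold_fraction=min_product_pct / 100.0,
        reference_objective=product_reaction,
    )
    desired_constraints: list[RegionConstraint] = [(biomass_reaction, ">=", bio_thr)]
    if desired_includes_product_floor:
        desired_constraints.append((product_reaction, ">=", prod_thr))
    desired = InterventionRegion(
        kind="desired",
        constraints=desired_constraints,
        threshold_fraction=min_biomass_pct / 100.0,
        reference_objective=biomass_reaction,
    )
    return target, desired


# ---------------------------------------------------------------------------
# verification (pure LP, independent of the MILP)
# ---------------------------------------------------------------------------

def verify_cut_set(
    model: MetabolicModel,
    cutset: CutSet | Iterable[str],
    target: InterventionRegion,
    desired: InterventionRegion,
) -> dict[str, bool]:
    """Check target-blocking, desired-feasibility, and support-minimality of a
    knockout set by plain LP feasibility tests."""
    reactions = (
        set(cutset.reactions) if isinstance(cutset, CutSet) else set(cutset)
    )
    t_cons = target.as_lp_constraints()
    d_cons = desired.as_lp_constraints()
    target_blocked = not lp.region_feasible(model, t_cons, reactions)
    desired_feasible = lp.region_feasible(model, d_cons, reactions)
    minimal = target_blocked
    if target_blocked:
        for rid in reactions:
            if not lp.region_feasible(model, t_cons, reactions - {rid}):
                minimal = False
                break
    flags = {
        "target_blocked": target_blocked,
        "desired_feasible": desired_feasible,
        "minimal": minimal,
    }
    if isinstance(cutset, CutSet):
        cutset.verified.update(flags)
    return flags


# ---------------------------------------------------------------------------
# Farkas-dual MILP enumeration
# ---------------------------------------------------------------------------

def _target_rows(
    target: InterventionRegion, rxn_index: Mapping[str, int], n: int
) -> tuple[np.ndarray, np.ndarray]:
    rows, rhs = [], []
    for rid, sense, val in target.constraints:
        row = np.zeros(n)
        if sense == "<=":
            row[rxn_index[rid]] = 1.0
            rows.append(row)
            rhs.append(val)
        elif sense == ">=":
            row[rxn_index[rid]] = -1.0
            rows.append(row)
            rhs.append(-val)
        else:
            raise ValueError(f"unsupported sense {sense!r} in target region")
    return np.vstack(rows), np.asarray(rhs)


def _build_milp(model: MetabolicModel, candidates: Sequence[str],
                target: InterventionRegion, big_m: float):
    """Assemble the sparse MILP matrices once; exclusion cuts are appended later.

    Variable layout: [u (m, free) | p (n, >=0) | q (n, >=0) | w (k, >=0) | z (nc, bin)].
    """
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    n, m = len(rxn_ids), len(met_ids)
    rxn_index = {r: i for i, r in enumerate(rxn_ids)}
    lbv = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ubv = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    T, t = _target_rows(target, rxn_index, n)
    k = T.shape[0]
    nc = len(candidates)
    cand_pos = {rid: i for i, rid in enumerate(candidates)}
    nvar = m + 2 * n + k + nc

    def cols(block, idx):
        offs = {"u": 0, "p": m, "q": m + n, "w": m + 2 * n, "z": m + 2 * n + k}
        return offs[block] + idx

    # dual stationarity D_j = (S'u)_j + p_j - q_j + (T'w)_j, relaxed for knocked j
    St = S.transpose().tocoo()
    rows, colix, vals = list(St.row), [cols("u", c) for c in St.col], list(St.data)
    for j in range(n):
        rows += [j, j]
        colix += [cols("p", j), cols("q", j)]
        vals += [1.0, -1.0]
    Tt = sparse.coo_matrix(T.T)
    rows += list(Tt.row)
    colix += [cols("w", c) for c in Tt.col]
    vals += list(Tt.data)
    D = sparse.coo_matrix((vals, (rows, colix)), shape=(n, nvar)).tocsr()

    constraints = []
    is_cand = np.zeros(n, dtype=bool)
    for rid in candidates:
        is_cand[rxn_index[rid]] = True
    # non-candidates: D_j = 0
    if (~is_cand).any():
        Dn = D[~is_cand]
        constraints.append(LinearConstraint(Dn, 0.0, 0.0))
    # candidates: -M z_j <= D_j <= M z_j  and  p_j, q_j <= M (1 - z_j)
    for rid in candidates:
        j = rxn_index[rid]
        zcol = cols("z", cand_pos[rid])
        dj = D[j].toarray().ravel()
        row_hi = dj.copy(); row_hi[zcol] -= big_m   # D_j - M z <= 0
        row_lo = dj.copy(); row_lo[zcol] += big_m   # D_j + M z >= 0
        rp = np.zeros(nvar); rp[cols("p", j)] = 1.0; rp[zcol] = big_m
        rq = np.zeros(nvar); rq[cols("q", j)] = 1.0; rq[zcol] = big_m
        constraints.append(
            LinearConstraint(
                sparse.csr_matrix(np.vstack([row_hi, -row_lo, rp, rq])),
                -np.inf,
                [0.0, 0.0, big_m, big_m],
            )
        )
    # Farkas objective row: ub'p - lb'q + t'w <= -1
    far = np.zeros(nvar)
    finite_ub = np.isfinite(ubv)
    finite_lb = np.isfinite(lbv)
    far[m : m + n][finite_ub] = ubv[finite_ub]
    far[m + n : m + 2 * n][finite_lb] = -lbv[finite_lb]
    far[m + 2 * n : m + 2 * n + k] = t
    constraints.append(LinearConstraint(sparse.csr_matrix(far), -np.inf, -1.0))

    # variable bounds; dual multipliers of absent (infinite) bound rows are 0
    lo = np.concatenate(
        [np.full(m, -big_m), np.zeros(2 * n), np.zeros(k), np.zeros(nc)]
    )
    hi = np.concatenate(
        [
            np.full(m, big_m),
            np.where(finite_ub, big_m, 0.0),
            np.where(finite_lb, big_m, 0.0),
            np.full(k, big_m),
            np.ones(nc),
        ]
    )
    integrality = np.concatenate([np.zeros(m + 2 * n + k), np.ones(nc)])
    c = np.zeros(nvar)
    c[m + 2 * n + k :] = 1.0  # minimize knockout count
    zslice = slice(m + 2 * n + k, nvar)
    return c, constraints, Bounds(lo, hi), integrality, zslice, nvar


def enumerate_mcs(
    model: MetabolicModel,
    candidates: Iterable[str],
    target: InterventionRegion,
    desired: InterventionRegion,
    max_size: int = 5,
    time_limit_s: float = 300.0,
    max_solutions: int = 100,
    big_m: float = BIG_M,
) -> list[CutSet]:
    """Enumerate support-minimal knockout sets blocking the target region while
    the desired region stays feasible, in nondecreasing cardinality.

    Enumeration stops at ``max_solutions``, ``max_size``, or the time limit
    (flagged on the result cell by :func:`threshold_sweep`, not an error).
    Every returned set has passed the independent LP verification.
    """
    candidates = sorted(set(candidates))
    unknown = set(candidates) - set(model.reactions)
    if unknown:
        raise KeyError(f"unknown candidate reactions: {sorted(unknown)}")
    if not lp.region_feasible(model, target.as_lp_constraints()):
        empty = CutSet(frozenset())
        verify_cut_set(model, empty, target, desired)
        return [empty]
    if not candidates:
        return []

    c, base_constraints, bounds, integrality, zslice, nvar = _build_milp(
        model, candidates, target, big_m
    )
    cuts: list[LinearConstraint] = []
    # cap cardinality
    card = np.zeros(nvar)
    card[zslice] = 1.0
    cuts.append(LinearConstraint(sparse.csr_matrix(card), -np.inf, float(max_size)))

    found: list[CutSet] = []
    t0 = time.monotonic()
    while len(found) < max_solutions:
        remaining = time_limit_s - (time.monotonic() - t0)
        if remaining <= 0:
            break
        with _quiet_native_stdout():
            res = milp(
                c,
                constraints=base_constraints + cuts,
                bounds=bounds,
                integrality=integrality,
                options={"time_limit": max(remaining, 0.1), "presolve": True},
            )
        if res.status == 2:  # infeasible: enumeration complete
            break
        if res.status == 1:  # hit the time limit mid-solve
            break
        if res.status != 0 or res.x is None:
            raise MILPBackendError(f"MILP backend failure: {res.message}")
        z = res.x[zslice]
        ko = frozenset(
            rid for rid, zi in zip(candidates, z) if zi > 0.5
        )
        if not ko:  # numerically empty solution: nothing left to enumerate
            break
        flags = verify_cut_set(model, ko, target, desired)
        if not flags["target_blocked"]:
            # Farkas certificate contradicted by LP re-check; exclude this
            # exact assignment only and continue (supersets may still block).
            row = np.zeros(nvar)
            for rid in candidates:
                row[zslice][candidates.index(rid)] = (
                    1.0 if rid in ko else -1.0
                )
            cuts.append(
                LinearConstraint(sparse.csr_matrix(row), -np.inf, len(ko) - 1)
            )
            continue
        # exclude this set and every superset
        row = np.zeros(nvar)
        for rid in ko:
            row[zslice][candidates.index(rid)] = 1.0
        cuts.append(LinearConstraint(sparse.csr_matrix(row), -np.inf, len(ko) - 1))
        if flags["desired_feasible"]:
            if not flags["minimal"]:  # pragma: no cover - big-M incompleteness
                warnings.warn(
                    f"skipping non-minimal MILP solution {sorted(ko)}; "
                    "consider raising big_m",
                    stacklevel=2,
                )
                continue
            cs = CutSet(reactions=ko, verified=dict(flags))
            found.append(cs)
    return found


# ---------------------------------------------------------------------------
# exhaustive oracle (certification path)
# ---------------------------------------------------------------------------

def exhaustive_mcs(
    model: MetabolicModel,
    candidates: Iterable[str],
    target: InterventionRegion,
    desired: InterventionRegion,
    max_size: int = 4,
) -> list[CutSet]:
    """Brute-force enumeration over all candidate subsets up to ``max_size``.

    Independent of the MILP path: every subset is tested by LP feasibility of
    the target and desired regions. Intended for small instances (certifying
    synthetic fixtures and cross-checking :func:`enumerate_mcs`).
    """
    candidates = sorted(set(candidates))
    t_cons = target.as_lp_constraints()
    d_cons = desired.as_lp_constraints()
    if not lp.region_feasible(model, t_cons):
        empty = CutSet(frozenset())
        verify_cut_set(model, empty, target, desired)
        return [empty]
    blocking: list[frozenset[str]] = []
    results: list[CutSet] = []
    for size in range(1, max_size + 1):
        for combo in combinations(candidates, size):
            ko = frozenset(combo)
            if any(b <= ko for b in blocking):
                continue  # superset of a smaller blocking set: not minimal
            if lp.region_feasible(model, t_cons, ko):
                continue
            blocking.append(ko)
            if lp.region_feasible(model, d_cons, ko):
                cs = CutSet(reactions=ko)
                verify_cut_set(model, cs, target, desired)
                results.append(cs)
    return results


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def threshold_sweep(
    model: MetabolicModel,
    product_reaction: str,
    biomass_reaction: str,
    thresholds: Sequence[float] = (0, 1, 5, 10, 30, 50),
    reference_model: MetabolicModel | None = None,
    candidates: Iterable[str] | None = None,
    max_size: int = 5,
    time_limit_s: float = 300.0,
    max_solutions: int = 100,
    desired_includes_product_floor: bool = False,
) -> SweepResult:
    """Sweep the (min_biomass_%, min_ACT_%) grid from relaxed to strict.

    Thresholds are percentages of the unmodified reference optima on the same
    medium. Grid cells record their cut sets, wall time, and whether the
    per-cell time limit was hit.
    """
    for pct in thresholds:
        if not 0 <= pct <= 100:
            raise ValueError(f"threshold percentages must lie in [0, 100]: {pct}")
    if candidates is None:
        candidates = preprocess_targets(model, objective=biomass_reaction)
    candidates = sorted(set(candidates))
    sweep = SweepResult()
    order = sorted(thresholds)
    for bio_pct in order:
        for act_pct in order:
            target, desired = build_regions(
                model,
                product_reaction,
                biomass_reaction,
                min_biomass_pct=bio_pct,
                min_product_pct=act_pct,
                reference_model=reference_model,
                desired_includes_product_floor=desired_includes_product_floor,
            )
            t0 = time.monotonic()
            cut_sets = enumerate_mcs(
                model,
                candidates,
                target,
                desired,
                max_size=max_size,
                time_limit_s=time_limit_s,
                max_solutions=max_solutions,
            )
            elapsed = time.monotonic() - t0
            for cs in cut_sets:
                cs.thresholds = (float(bio_pct), float(act_pct))
            sweep.grid.append(
                {
                    "min_biomass_pct": float(bio_pct),
                    "min_act_pct": float(act_pct),
                    "cut_sets": cut_sets,
                    "wall_time_s": elapsed,
                    "hit_time_limit": elapsed >= time_limit_s,
                }
            )
    return sweep
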