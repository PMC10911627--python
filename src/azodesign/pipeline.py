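"""End-to-end workflow driver.

Runs the full strain-design sequence on one model/medium configuration:
load -> medium -> FBA/FVA + production envelopes -> cofactor flux-sums ->
knockout-candidate preprocessing -> threshold sweep of cut-set enumeration ->
gene-level agreement -> design evaluation -> pathway utilization; every
stage's tables land in the output directory as CSV/JSON plus a text summary.
Reruns with identical configuration are bit-identical (timestamps are
confined to the log).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cmcs, lp, strain_eval
from .model import MediumSpec, MetabolicModel, apply_medium, read_sbml
from .synthetic import ToySpec, demo_medium, make_demo_model, make_toy_model

DEFAULT_THRESHOLDS = (0, 1, 5, 10, 30, 50)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    model: str = "toy:aromatic"  # toy:<mode> | demo | path to SBML
    medium: str = "none"  # none | mr | glc | glc_mr | path to JSON limits
    biomass_reaction: str = "BIOMASS"
    product_reaction: str = "EX_prod_e"
    substrate_exchange: str = "EX_suba_e"
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    max_cutset_size: int = 4
    time_limit_s: float = 300.0
    max_solutions: int = 50
    out_dir: str = "results/run"
    seed: int = 0

    def validate(self) -> None:
        for pct in self.thresholds:
            if not 0 <= pct <= 100:
                raise ConfigError(f"threshold {pct} outside [0, 100]")
        if self.model not in ("demo",) and not self.model.startswith("toy:"):
            if not Path(self.model).exists():
                raise ConfigError(f"model file {self.model!r} does not exist")
        if self.medium not in ("none", "mr", "glc", "glc_mr") and not Path(self.medium).exists():
            raise ConfigError(f"unknown medium {self.medium!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key = value configuration with ``include`` support."""
        values: dict[str, object] = {}

        def load(p: Path) -> None:
            for raw in p.read_text().splitlines():
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{p}: cannot parse line {raw!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                if key == "include":
                    load((p.parent / val).resolve())
                    continue
                try:
                    values[key] = json.loads(val)
                except json.JSONDecodeError:
                    values[key] = val

        load(Path(path))
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "thresholds" in values:
            values["thresholds"] = tuple(values["thresholds"])  # type: ignore[arg-type]
        return cls(**values)  # type: ignore[arg-type]


def _log(handle, stage: str, **fields) -> None:
    line = " ".join([f"stage={stage}"] + [f"{k}={v}" for k, v in fields.items()])
    print(line, file=sys.stderr)
    handle.write(line + "\n")
    handle.flush()


def load_configured_model(config: RunConfig) -> MetabolicModel:
    if config.model == "demo":
        return make_demo_model()
    if config.model.startswith("toy:"):
        mode = config.model.split(":", 1)[1]
        return make_toy_model(ToySpec(substrate_mode=mode, seed=config.seed)).model
    return read_sbml(config.model)


def load_configured_medium(config: RunConfig) -> MediumSpec | None:
    if config.medium == "none":
        return None
    if config.medium in ("mr", "glc", "glc_mr"):
        return demo_medium(config.medium)
    limits = json.loads(Path(config.medium).read_text())
    return MediumSpec(uptake_limits=limits, name=Path(config.medium).stem)


def run_reproduction(config: RunConfig) -> dict:
    """Execute the full workflow; returns a bundle of result paths/values."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.__dict__ | {"thresholds": list(config.thresholds)}}
    log = open(out / "run.log", "a")
    t_start = time.monotonic()

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                result = fn()
            except Exception as exc:
                _log(log, name, status="failed", error=repr(exc))
                (out / "partial_state.json").write_text(
                    json.dumps(bundle, indent=2, default=str)
                )
                raise StageError(name, exc) from exc
            _log(log, name, status="ok", elapsed=f"{time.monotonic() - t0:.2f}s")
            return result

        return wrap

    model = stage("load_model")(lambda: load_configured_model(config))
    medium = load_configured_medium(config)
    if medium is not None:
        model = stage("apply_medium")(lambda: apply_medium(model, medium))
    for rid in (config.biomass_reaction, config.product_reaction):
        if rid not in model.reactions:
            raise ConfigError(f"reaction {rid!r} not present in the model")

    # optimality and envelopes
    def fba_stage():
        growth = lp.fba(model, objective=config.biomass_reaction)
        product = lp.fba(model, objective=config.product_reaction)
        return {
            "growth_optimum": growth.objective_value,
            "max_product": product.objective_value,
        }

    bundle["optima"] = stage("fba")(fba_stage)

    def envelope_stage():
        rows = []
        pairs = [(config.product_reaction, config.biomass_reaction)]
        if config.substrate_exchange in model.reactions:
            pairs.append((config.substrate_exchange, config.biomass_reaction))
            pairs.append((config.substrate_exchange, config.product_reaction))
        for x_rxn, y_rxn in pairs:
            env = lp.production_envelope(model, x_rxn, y_rxn, n_points=25)
            for x, lo, hi in env.as_rows():
                rows.append(
                    {"x_reaction": x_rxn, "y_reaction": y_rxn,
                     "x": x, "y_min": lo, "y_max": hi}
                )
        df = pd.DataFrame(rows)
        df.to_csv(out / "envelopes.csv", index=False)
        return str(out / "envelopes.csv")

    bundle["envelopes"] = stage("envelopes")(envelope_stage)

    def fluxsum_stage():
        cofactors = [m for m in ("nadh_c", "atp_c", "nad_c", "adp_c") if m in model.metabolites]
        rows = []
        for obj in (config.biomass_reaction, config.product_reaction):
            res = lp.fba(model, objective=obj, tie_break=True)
            if not res.optimal:
                continue
            report = lp.flux_sum(model, res, metabolites=cofactors)
            for met in cofactors:
                rows.append({"objective": obj, "metabolite": met,
                             "flux_sum": report[met]})
        df = pd.DataFrame(rows)
        df.to_csv(out / "flux_sums.csv", index=False)
        return {f"{r['objective']}:{r['metabolite']}": r["flux_sum"] for r in rows}

    bundle["flux_sums"] = stage("flux_sums")(fluxsum_stage)

    candidates = stage("preprocess")(
        lambda: sorted(cmcs.preprocess_targets(model, objective=config.biomass_reaction))
    )
    bundle["n_candidates"] = len(candidates)

    def sweep_stage():
        sweep = cmcs.threshold_sweep(
            model,
            config.product_reaction,
            config.biomass_reaction,
            thresholds=config.thresholds,
            candidates=candidates,
            max_size=config.max_cutset_size,
            time_limit_s=config.time_limit_s,
            max_solutions=config.max_solutions,
        )
        (out / "cutset_sweep.json").write_text(
            json.dumps(sweep.to_dict(), indent=2, sort_keys=True)
        )
        return sweep

    sweep = stage("threshold_sweep")(sweep_stage)
    unique_sets = sorted(
        {cs.reactions for cell in sweep.grid for cs in cell["cut_sets"] if cs.reactions},
        key=lambda s: (len(s), sorted(s)),
    )
    bundle["n_cut_sets"] = len(unique_sets)

    def design_stage():
        reports = []
        target, desired = cmcs.build_regions(
            model, config.product_reaction, config.biomass_reaction, 0, 0
        )
        baseline = strain_eval.evaluate_design(
            model, frozenset(), config.substrate_exchange, config.product_reaction,
            design_id="baseline",
        )
        reports.append(baseline)
        for i, reactions in enumerate(unique_sets, start=1):
            cs = cmcs.CutSet(reactions=reactions)
            cmcs.verify_cut_set(model, cs, target, desired)
            check = strain_eval.gene_level_check(model, cs, target, desired)
            reports.append(
                strain_eval.evaluate_design(
                    model, cs, config.substrate_exchange, config.product_reaction,
                    design_id=f"design_{i}", genes=check.genes,
                )
            )
        df = strain_eval.table3(reports)
        df.to_csv(out / "design_table.csv", index=False)
        return [r.to_dict() for r in reports]

    bundle["designs"] = stage("design_evaluation")(design_stage)

    def utilization_stage():
        available = [m for m in strain_eval.KEY_METABOLITES if m in model.metabolites]
        fallback = [m for m in ("cc_c", "nadh_c", "atp_c") if m in model.metabolites]
        mets = available or fallback
        if not mets:
            return None
        util = strain_eval.pathway_utilization(
            model, objective=config.biomass_reaction, key_metabolites=mets
        )
        rows = [
            {"metabolite": met, "total_producing_flux": util.totals[met],
             "producers": ";".join(f"{r}:{v:.6g}" for r, v in util.producers[met])}
            for met in mets
        ]
        pd.DataFrame(rows).to_csv(out / "pathway_utilization.csv", index=False)
        return {r["metabolite"]: r["total_producing_flux"] for r in rows}

    bundle["pathway_utilization"] = stage("pathway_utilization")(utilization_stage)

    summary = [
        f"model: {model.id}",
        f"medium: {medium.name if medium else 'as-declared bounds'}",
        f"growth optimum: {bundle['optima']['growth_optimum']:.6g}",
        f"max product flux: {bundle['optima']['max_product']:.6g}",
        f"knockout candidates: {bundle['n_candidates']}",
        f"unique cut sets: {bundle['n_cut_sets']}",
    ]
    for rep in bundle["designs"]:
        if rep["design_id"] == "baseline":
            continue
        summary.append(
            f"{rep['design_id']}: growth={rep['growth']:.4g} "
            f"product={rep['product_flux']:.4g} yield={rep['yield_at_optimum_growth']:.4g} "
            f"bpcy={rep['bpcy']:.4g} gene_agreement={rep['gene_agreement']}"
        )
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    bundle["summary"] = summary
    _log(log, "done", elapsed=f"{time.monotonic() - t_start:.2f}s")
    log.close()
    return bundle
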