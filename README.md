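# azodesign

Constraint-based strain design for valorizing azo dyes: can an industrial
dye pollutant such as methyl red (MR) serve as the carbon source for
microbial production of a polyketide such as actinorhodin (ACT)? The package
implements the full in-silico workflow for answering that question in a
*Pseudomonas putida*-style production host: editing a stoichiometric model to
graft the dye-to-polyketide pathway on, mapping the production space,
accounting for redox-cofactor turnover, finding the minimal knockout sets
that make product export an obligatory by-product of growth, and evaluating
the resulting strain designs.

It is aimed at metabolic engineers and systems-biology researchers who work
with genome-scale models (SBML) and want a transparent, solver-explicit
implementation of growth-coupling by constrained minimal cut sets.

## The science in brief

All analyses live on the flux cone of a stoichiometric model: steady state
`S·v = 0` with bounds `lb ≤ v ≤ ub`.

- **FBA / FVA / envelopes** — flux balance analysis maximizes one flux
  (growth, product export) by LP; flux variability analysis reports each
  flux's attainable interval; a production envelope traces `(x, y_min, y_max)`
  by fixing one flux on a grid and optimizing the other.
- **Flux-sum** — the turnover of metabolite *i* at a flux state *v* is
  `Φ_i = ½ Σ_j |S_ij v_j|`; at steady state production equals consumption, so
  Φ measures how hard a cofactor pool (NADH, ATP) is cycling.
- **Constrained minimal cut sets (cMCS)** — a support-minimal set of reaction
  knockouts that makes the *target* region (product flux at or below a
  threshold) infeasible while the *desired* region (growth above a threshold)
  stays feasible. After such knockouts the cell cannot reach any low-product
  flux state: production is growth-coupled. Enumeration uses a Farkas-dual
  MILP with binary knockout indicators; every reported set is re-verified by
  independent LPs (blocking, viability, minimality).
- **Design metrics** — product yield = product flux / substrate uptake, and
  the biomass-product coupled yield `BPCY = yield × growth`, plus the
  minimum guaranteed yield (worst-case product flux at near-zero growth) and
  gene-level knockout agreement through GPR boolean logic (isoenzymes: all
  genes; complexes: one subunit).

The mechanism that makes the dye special: reductive cleavage of MR consumes
2 NADH (azoreductase) and another NADH downstream (anthranilate
dioxygenase), while sugar catabolism *produces* NADH. On the dye, knocking
out the cell's other NADH sources forces flux through the ACT pathway — a
net NADH regenerator — whenever the cell is alive. On glucose the same trick
fails because catabolism over-supplies redox power. The package ships
certified synthetic networks exhibiting exactly this dichotomy, so the whole
pipeline is testable without any external model file.

## Worked example

```bash
$ azodesign fba --model toy:aromatic --objective BIOMASS
BIOMASS max = 3.8
```

The certified aromatic toy grows at 3.8 h⁻¹ (an exact rational optimum,
19/5, stored in the fixture metadata). Sweep for coupling cut sets and
evaluate the design:

```python
from azodesign import cmcs, strain_eval
from azodesign.synthetic import make_toy_model

bundle = make_toy_model()                       # aromatic substrate mode
model = bundle.model
target, desired = cmcs.build_regions(model, "EX_prod_e", "BIOMASS", 0, 0)
cuts = cmcs.enumerate_mcs(model, cmcs.preprocess_targets(model), target, desired)
print(sorted(cuts[0].reactions))                # ['NS1', 'NS2']
check = strain_eval.gene_level_check(model, cuts[0], target, desired)
report = strain_eval.evaluate_design(model, cuts[0], "EX_suba_e", "EX_prod_e",
                                     genes=check.genes)
print(report.growth, report.product_flux, report.yield_at_optimum_growth)
# 2.25 7.75 0.775
```

Knocking out the two alternative NADH sources (`NS1`, `NS2` — genes
`gNS1a`, `gNS1b`, `gNS2`) leaves the product pathway as the only way to
regenerate NADH for dye catabolism and maintenance: growth drops from 3.8 to
2.25 h⁻¹ but every viable flux state now exports at least 1 unit of product
(yield 0.775, BPCY 1.74).

The same workflow on the bundled named-metabolite demo host reproduces the
substrate contrast end to end:

```bash
$ python analysis/04_cutset_sweep.py
[demo_mr] 10 grid hits, 1 unique cut sets: [['TCA']]
[demo_glc] 0 grid hits, 0 unique cut sets: none
[demo_glc_mr] 10 grid hits, 1 unique cut sets: [['GLYC', 'TCA']]
```

Coupling designs exist on the dye (knock the TCA lump, gene `gltA`), none
exist on glucose, and the mixed medium needs glycolysis severed too — while
the maximum ACT flux on MR exceeds glucose by 20%
(`analysis/02_production_envelopes.py`).

The numbered scripts under `analysis/` run the study sequence (build models →
envelopes → cofactor flux-sums → cut-set sweeps → design tables) and write
their tables under `results/`.

## Genome-scale models

All operations accept any SBML model with fbc bounds and GPRs
(`azodesign.read_sbml`). The genome-scale analyses of the engineered
*P. putida* host (iJN1462c) additionally need its supplementary SBML file,
which is not redistributable here: drop it at `data/reference/iJN1462c.xml`
and the reference-scale tests in `tests/test_acceptance.py` (production
ceilings, envelope coordinates, the published design table) become runnable;
without it they fail with an explicit message. `azodesign.reference` holds
the medium conventions (MR uptake deliberately unconstrained at 1000
mmol gDW⁻¹ h⁻¹, O₂ at 30) and the published knockout tables.
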