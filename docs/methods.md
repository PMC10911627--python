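# Methods

## Model and assumptions

Everything operates on a stoichiometric metabolic model: metabolites with
compartments (`c`/`p`/`e` by convention, extensible), reactions with real
coefficient maps, flux bounds in mmol gDW⁻¹ h⁻¹ (the biomass pseudo-reaction
in h⁻¹), and gene-protein-reaction (GPR) boolean rules (AND = complex
subunits, OR = isoenzymes). The feasible set is the flux cone
`{v : S v = 0, lb ≤ v ≤ ub}` — purely stoichiometric, quasi-steady-state;
no kinetics, regulation, or thermodynamic constraints are represented, and
conclusions inherit those limits.

Sign conventions: negative stoichiometric coefficients are consumed;
exchange flux is negative for uptake. A `MediumSpec` stores positive uptake
magnitudes and `apply_medium` sets `lower_bound = -limit` on listed
exchanges, closing uptake on all unlisted ones while never touching
secretion bounds. Editing operations (`apply_reaction_knockouts`,
`apply_gene_knockouts`, `apply_medium`, pathway addition) are pure functions
returning copies, so one wild-type model serves many simulated strains.

SBML is read and written through cobrapy/libsbml (fbc-v2 emitted, legacy
bounds accepted on read); the solver path is scipy's HiGHS throughout —
`linprog` for every LP, `milp` for the cut-set MILP. cobrapy's own
FBA/FVA (GLPK backend) appears only in the test suite as an independent
cross-check, never as the implementation.

## Linear-programming layer

* **FBA** maximizes/minimizes one flux. Objective values are unique;
  flux vectors are not. Wherever a single representative vector is reported
  (flux-sums, pathway utilization, design tables) a parsimonious tie-break
  is applied: minimize `Σ|v|` (split variables) with the objective fixed at
  its optimum. Reported headline numbers are objective values or envelope
  coordinates, which are vertex-independent.
* **FVA** solves two LPs per reaction, optionally with the objective held at
  a fraction of its optimum. Reversible reactions are handled on the net
  flux directly; direction splitting exists only inside the MILP encoding.
* **Production envelopes** fix the x-flux on an evenly spaced grid spanning
  its FVA range (default 40 points, endpoints included) and solve min/max of
  the y-flux at each point. Grid points that are marginally infeasible in
  floating point are retried with a `1e-7`-scaled nudge toward the interior.
  A blocked x-reaction yields a single-point envelope with a warning.
* **Flux-sum**: `Φ_i = ½ Σ_j |S_ij v_j|`, with producing and consuming
  contributions listed separately; conservation (producing = consuming)
  holds by steady state and is asserted in tests.
* **Blocked reactions**: FVA interval within `ε_block = 1e-9` of zero.
  **Essential** reactions/genes: single knockout drives the FBA optimum
  below `growth_floor = 1e-6` h⁻¹ (or renders the model infeasible).

## Cut-set enumeration

The target region appends linear rows `T v ≤ t` (product flux at or below a
threshold) to the flux cone. By LP duality the region is infeasible exactly
when a Farkas certificate exists:

    Sᵀu + p − q + Tᵀw = 0,   ubᵀp − lbᵀq + tᵀw ≤ −1,   p, q, w ≥ 0.

Knocking out candidate reaction `j` sets its bounds to zero, which in the
dual frees its stationarity row and removes its bound terms. With binary
indicators `z_j` this becomes: `|D_j| ≤ M z_j` on the stationarity residual
and `p_j, q_j ≤ M (1 − z_j)`, with `M = 10⁴` by default. Minimizing `Σ z`
and adding superset-exclusion cuts (`Σ_{j∈K} z_j ≤ |K| − 1`) enumerates
solutions in nondecreasing cardinality. Dual multipliers of absent (infinite)
bounds are pinned to zero.

Design choices worth knowing:

* **Desired-region feasibility is a post-check LP**, not part of the MILP.
  Anti-monotonicity makes this sound: if growth is infeasible under K it is
  infeasible under every superset, so the same exclusion cut applies whether
  a candidate set is accepted or rejected. Every accepted set is verified by
  independent LPs (target blocked, desired feasible, single-removal
  minimality) — soundness is asserted in code. A Farkas certificate proves
  infeasibility regardless of `M`; an undersized `M` can only cost
  completeness, which the oracle-equivalence tests would catch at desk scale.
* **One binary per reaction**: a knockout always zeroes both directions.
* **Thresholds** are percentages of the FBA optima of the *unmodified*
  reference model on the same medium — the only self-consistent reading. A
  0% threshold is resolved as a strict-positivity demand at `1e-6` of the
  respective optimum (the literal degenerate region would make "0%" either
  trivial or meaningless). Whether the desired region should also demand the
  product floor is genuinely ambiguous; both readings are implemented
  (`desired_includes_product_floor`), defaulting to growth-only.
* **Sweep order** is relaxed-to-strict over the (biomass %, product %) grid;
  per-cell time limit defaults to 300 s, configurable, with a
  `hit_time_limit` flag rather than an error. Wall times stay in logs so
  serialized sweeps are byte-reproducible.
* `preprocess_targets` removes five candidate categories before enumeration:
  blocked, essential, gene-less, transport/peripheral (spanning ≥ 2
  compartments, or listed in `model.peripheral_reactions`), and boundary
  reactions (all-same-sign stoichiometry). Candidates are medium-specific.
* `exhaustive_mcs` is the brute-force reference path (all candidate subsets
  by LP); it certifies synthetic fixtures at generation time and
  cross-checks the MILP in tests.

## Gap filling

Exhaustive search by cardinality over candidate reactions (singles, then
pairs, …), adding each subset to a copy of the model and testing whether the
objective optimum exceeds `1e-6`. This mirrors the manual FBA-driven design
loop it automates, is deterministic (ties broken by candidate order), and is
verifiable against subset enumeration; it is intended for curated candidate
lists, not database-scale universal sets.

## Strain evaluation

* **Gene resolution**: among the inclusion-minimal gene sets falsifying a
  reaction's GPR, prefer the one using fewest pleiotropic genes (genes
  appearing in any other reaction's GPR), then smallest, then lexicographic.
  This reproduces the field's rules — all isoenzyme genes for OR, one
  subunit for AND, pleiotropy avoided when possible. Agreement holds when
  the gene-knocked model blocks the target and keeps the desired region
  feasible exactly as the reaction-knocked model does, and the gene knockout
  disables at least the cut-set reactions.
* **Design metrics** come from the tie-broken biomass-optimal state: growth,
  |substrate exchange|, product flux, yield = product/uptake, BPCY =
  yield × growth. Gene knockout counts above 25 are flagged as
  experimentally unreasonable.
* **Minimum guaranteed yield** is defined operationally by a two-stage LP:
  (1) minimize product flux subject to viability (growth ≥ 10⁻⁶ of the
  design's optimum); (2) at that product flux, maximize substrate uptake;
  the ratio is the conservative worst case. The alternative reading —
  dividing by the uptake at the growth optimum — is reported alongside
  (`min_guaranteed_yield_alt`), since the published tables do not pin down
  the denominator.
* **Pathway utilization** sums positive `S_ij v_j` contributions per key
  metabolite at the tie-broken optimum and records producer identities and
  directions. The default list holds the 23 representative central-carbon
  metabolites (glycolysis/gluconeogenesis, TCA, EMP/ED/PP, glyoxylate shunt,
  aromatic catabolism, amino-acid biosynthesis) in BiGG-style ids,
  overridable per call.

## Synthetic fixtures

`make_toy_model` generates an abstract 12–25 reaction network holding
exactly the structural features the analysis exploits: a two-step substrate
transport chain, a central carbon node, an NADH/NAD cycle closed by
respiration, ATP maintenance (lower-bounded), biomass, a product pathway
regenerating `product_nadh_yield` NADH, and `planted_cutset_size`
alternative NADH sources. In **aromatic** mode catabolism consumes NADH and
knocking out the planted sources growth-couples the product; in **sugar**
mode catabolism over-supplies NADH relative to the biomass ATP cost
(`nadh_per_sugar > biomass_atp_cost`), which is precisely why no coupling
cut set exists; **both** mode carries both entries and its planted set
additionally contains the sugar catabolism reaction. `ToySpec.validate`
rejects parameter combinations that break these regimes (e.g. a product
pathway that does not out-yield the aromatic NADH cost).

Certification happens at generation time, not test time: closed-form
rational optima (exact `Fraction` arithmetic) must agree with fresh LP
solves to 10⁻⁷; a stored rational flux vector must satisfy `S v = 0`
*exactly* and attain the stated optimum; and the exhaustive oracle must
return exactly the planted family (aromatic/both) or the empty family
(sugar) up to planted-size + 1. Any violation raises instead of producing a
fixture. Default conditions: uptake limit 10 mmol gDW⁻¹ h⁻¹, maintenance 1,
biomass ATP cost 2, aromatic NADH cost 1, product NADH yield 2, primary
source yield 3 — small integers keeping every optimum exactly representable.

`make_demo_model` is a named-metabolite emulation of the engineered host
(~29 reactions): glucose entry with lumped glycolysis, pyruvate
dehydrogenase, a lumped TCA cycle, native catechol meta-cleavage, oxidative
phosphorylation (P/O = 2), acetyl-CoA carboxylase, ATP maintenance at
0.92 mmol gDW⁻¹ h⁻¹ (the published non-growth maintenance for *P. putida*),
and a biomass reaction drawing acetyl-CoA + pyruvate + 6 ATP. The bundled
dye block grafts on the azoreductase with its printed stoichiometry (2 NADH
per MR) and transports; the ACT block is a *synthetic* lump — anthranilate
1,2-dioxygenase with literature stoichiometry plus one reaction condensing
2 acetyl-CoA + 14 malonyl-CoA per ACT with 8 NADH regenerated, sized so the
pathway is a net redox/energy source, the property growth-coupling needs.
On this host the workflow reproduces the qualitative substrate contrast:
a one-knockout coupling design on MR (the TCA lump), none on glucose, a
two-knockout design on the mixed medium, and a ~20% higher ACT ceiling on
the dye than on glucose.

What the fixtures do **not** emulate: realistic *P. putida* physiology
(byproduct spectra, proton/charge balancing beyond the MR block, growth
yields), genome-scale redundancy, or realistic GPR complexity. Passing
tests therefore demonstrate correctness of the algorithms and the
qualitative coupling logic, not quantitative predictions for the real
organism; genome-scale numbers require the supplementary reference SBML
(see README) and are checked only when it is present.

## Numerical choices

LP feasibility tolerance 10⁻⁹ (HiGHS defaults govern the solves; derived
quantities are compared at 10⁻⁶–10⁻⁷), `ε_block = 10⁻⁹`,
`growth_floor = 10⁻⁶ h⁻¹`, coupling epsilon `10⁻⁶ ×` the respective optimum,
big-M `10⁴`, per-cell MILP time limit 300 s (60–120 s in tests and analysis
scripts to keep runs in seconds), envelope grids of 20–40 points in tests
and analyses. Duplicate reaction additions are a hard error unless
explicitly skipped — silent duplication would corrupt the stoichiometric
matrix. Degenerate inputs (blocked envelope axes, infeasible designs, empty
media) return flagged results rather than raising wherever the result is
scientifically meaningful.

## Known limitations

* Cut-set solution *counts* at genome scale depend on solver and time
  budget and are not reproduced; the package substitutes oracle-equivalence
  and verification checks (see tests).
* Gene-level constraints are not encoded inside the MILP; gene agreement is
  a post-hoc check, so reaction-level designs without a consistent gene
  implementation are reported with `gene_agreement = False` rather than
  excluded during search.
* The exhaustive oracle and the certification step scale exponentially in
  candidate count and are deliberately restricted to small instances.
* `min_guaranteed_yield` at near-zero growth can be sensitive to the
  viability epsilon on models where maintenance alone forces product flux.
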