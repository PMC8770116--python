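# Methods

This note documents the models implemented in `migrisk`, the parameters
that matter, the synthetic data used to exercise them, and the design
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Mechanistic migration model

The mouthed product is modelled as a one-sided homogeneous slab of
thickness `d_p` (cm) containing the chemical at concentration `C0`
(µg/g), in contact with a finite, well-mixed saliva volume `V_f` (cm³).
Migration is Fickian diffusion inside the slab coupled to equilibrium
partitioning at the surface, with partition coefficient `K_pf` (= the
material–saliva coefficient `K_ms`). Two dimensionless quantities govern
the kinetics:

* the **capacity ratio** `α = (1/K_pf)·(V_f/V_p)` — the saliva side's
  equilibrium capacity relative to the product; the migrated fraction
  saturates at `α/(1+α)`;
* the **reduced time** `D_p·t/d_p²`.

For `t ≤ t_dev` the migrated fraction is the thin-slab short-term
solution `f_ts = (2/d_p)·√(D_p·t/π)` (√t growth). For `t > t_dev` a
two-exponential relaxation interpolates from `f(t_dev)` to the
equilibrium plateau, with rate parameter
`β = (1/d_p)·√(D_p/(π·t_dev)·(α/(1+α) − f(t_dev)))` and weights A, B, C
that are clamped power laws of α (A ∈ [0.7, 1], B ∈ [0.3, 0.9]; C drops
to the constant 0.004 below its 0.3 threshold and clamps at 1 above —
the asymmetric C rule is implemented exactly as published for this model
family, isolated in one function should its source ever be revised).
`t_dev` scales exactly as `d_p²/D_p`, with an empirical α-dependent
prefactor: logistic in log α above α = 0.2, a power law below.

**Assumptions.** One-sided migration under the mouthed area; no
concentration dependence of `D_p` (the saturation observed for very high
plasticizer loadings is not modelled); a single implied temperature; no
uptake modelling across mouth/GI barriers; organic chemicals only
(migration models for metals/inorganics are out of scope).

**Numerical choices.**

* `log(α)` in the empirical correlations is base-10, centralised in a
  single helper. Under log10 the two `t_dev` branches agree within a few
  percent at α = 0.2; the natural-log reading leaves a >2× mismatch, so
  log10 is also the internally consistent reading.
* Branch continuity at `t_dev` is exact by construction (both branches
  evaluate to `f(t_dev)` there); the suite verifies it to <1e−12.
* The bound `0 ≤ f_mgr ≤ α/(1+α)` is enforced by clamping with a
  structured warning rather than raising, because inventory screening
  must survive pathological edge rows (e.g. α so small that the
  already-migrated fraction exceeds the equilibrium capacity; the β
  radicand is then negative and β is set to 0).
* Internal units are cm, s, µg. The single unit conversion to
  µg/10 cm²/min happens once, in `migration_rate`.

**Rate conversion.** `R_mgr = f_mgr·m₀/(A_contact·t)`, with the initial
mass convention `m₀ = C0 × material density × (A_contact × d_p)`: the
chemical mass in the one-sided slab engaged in migration under the
mouthed area. This makes `R_mgr` independent of total product size and
exactly linear in `C0`, consistent with the per-10 cm² normalisation.
`t = 0` leaves the fraction defined but the rate undefined (explicit
error).

## Property QSPRs

The model needs `D_p` and `K_ms` per chemical–material pair. Both come
from coefficient tables loaded at runtime (`data/materials.yaml`), so
published coefficient sets can be swapped in without code changes. The
functional forms are fixed:

* `log10 D_p = a + b·MW`, with `b ≤ 0` enforced at load time (diffusion
  never speeds up with molecular size). An `mw_domain` per material marks
  the applicability range; outside it the estimate is returned with a
  structured warning (extrapolation, not refusal).
* `log10 K_ms = a + b·log10 Kow − c·(EtOH-eq/100)`, with `b, c ≥ 0`
  enforced, making K_ms non-decreasing in Kow and non-increasing in
  EtOH-eq unconditionally. `log10 Kow` is capped at 11, the high end of
  the partition QSPR's applicability domain, before evaluation (with a
  warning). The EtOH-eq term is additive rather than an interaction with
  log Kow: an interaction form would invert the EtOH-eq monotonicity for
  hydrophilic chemicals (log Kow < 0), which the additive form avoids.

**EtOH-eq policy.** Saliva is treated as a food simulant characterised
by its ethanol-equivalency: 20 % for quiescent in-vitro experiments,
50 % for in-vivo or mechanically agitated conditions (saliva in a real
mouth exchanges rapidly with surrounding tissue, whose EtOH-eq is that
of flesh), and 50 % as the recommended conservative setting.

**Shipped coefficients are representative, not transcribed.** The
published coefficient values for these QSPRs live in supplementary
material and secondary sources not redistributable here. The YAML file
ships constructed defaults chosen once to reproduce the documented
qualitative structure — diffusion coefficients in wood, silicone and EVA
roughly three orders of magnitude above PVC/PP at equal MW, K_ms driven
primarily by Kow with a weak material effect — and is labelled as such
in its header and provenance strings. All quantitative claims made by the
test suite concern the synthetic data generated *with* these
coefficients, and are therefore internally consistent; users wanting
literature-comparable numbers should install a published coefficient
set.

## Regression model and forward selection

The alternative predictor is OLS on the log10 scale with candidates
{log10 C0, log10 D_p, log10 Kow, log10 K_ms, log10 MW}. Classic forward
selection: at each step the candidate with the smallest partial-t
p-value below `entry_alpha` (default 0.05, configurable) enters; ties
break by candidate order; numerically collinear candidates are skipped;
an exactly constant response short-circuits to the intercept-only model
(float rounding in OLS can otherwise manufacture spurious
significance). Selection is fully deterministic. The fitted model
document records coefficients, p-values, 95 % CIs, fit R², fit Sₑ, n,
and the units of every predictor, so a model cannot silently be applied
to inputs in other units. The shipped default model
(`data/eq5_model.json`) is the published three-predictor fit
(intercept 3.23; slopes 0.73 on log10 D_p, 0.92 on log10 C0, −0.06 on
log10 Kow).

## Harmonized dataset and synthetic generation

The dataset schema is a frozen CSV (UTF-8, comma, snake_case headers
with units embedded) with one row per experimental observation. Reading
collects row-level violations as row-numbered diagnostics and never
fails on a bad row; only a missing mandatory column is fatal. Chemical
identity is keyed on CAS when present (checksum-validated), else on the
normalised name; duplicate observations across studies remain distinct.
Raw study reports standardize to µg/10 cm²/min from any of three
representations (migrated mass; fraction × initial mass; final
concentration × saliva volume). Products map to archetypes by material —
PVC/PP/wood → doll, silicone/EVA → pacifier — with per-record overrides
honoured.

**Synthetic generator.** The generator emulates the harmonized dataset's
structure: 437 observations of 60 chemicals (66 chemical–material
combinations, 6 chemicals appearing in a second material, 18 study
labels) across 5 materials, drawn from group templates (phthalates and
alternative plasticizers in PVC/PP, parabens in EVA, polybrominated
diphenyl ethers in PP/PVC, methylsiloxanes in silicone, chlorophenols in
wood, fragrance allergens in PP/wood) with group-plausible MW and
log Kow ranges. `C0` is log-uniform over 10–10⁵ µg/g, contact times
log-uniform over 5–240 min, 10 % of rows in vivo and 30 % agitated.
"True" rates come from the mechanistic model with QSPR inputs under the
allocated archetype geometry; observed rates multiply the truth by
`10^N(0, σ)` with σ = 0.79 decades by default — the published log-scale
scatter between model and measurement, the one stated dispersion for
these study conditions. Everything is reproducible from one seed.

**What passing tests show — and don't.** The synthetic data share the
real dataset's schema, scale, group/material structure and noise
magnitude, but their rates are generated *by the implemented model
itself*: closed-loop tests therefore verify internal consistency,
pipeline correctness and statistical behaviour (e.g. that cross-validation
degrades gracefully when whole chemical groups are held out), not
predictive accuracy against laboratory measurements. The latter requires
importing the published workbook (`scripts/import_si_workbook.py`).

## Validation metrics and cross-validation

Accuracy is judged against the 1:1 line on the log10 scale:
`Sₑ = √(Σ(log10 pred − log10 obs)²/n)` and `R² = 1 − SSres/SStot`. The
Sₑ divisor is `n` by default — the 1:1 comparison line is fixed, not
fitted, so no degrees of freedom are consumed — with a `ddof=1` toggle
for n−1 conventions. R² is not clamped and can be negative for
predictors worse than the observed geometric mean. Three CV schemes:
leave-chemical-group-out, leave-study-out, and seeded tenfold random CV
stratified by material (so no fold loses a material entirely). The
mechanistic predictor involves no fitting, so its pooled CV metrics
equal its whole-dataset metrics by construction — a property the suite
asserts; the regression predictor is refit per training fold.

## Exposure scenarios and risk screening

`E = Δt·(A_contact/10 cm²)·R_mgr/BW`. The four built-in scenarios cross
two age groups (3 to <6 months, BW 7.4 kg; 2 to <3 years, BW 13.8 kg)
with average and 99th-percentile mouthing durations per product
archetype (min/h: 3.4/0.5 and 37.3/2.5 for the younger group's
pacifier/doll; 1.8/0.4 and 46.3/2.9 for the older). Durations are
day-averaged rates, so `active_hours_per_day` defaults to 24; it is an
explicit scenario parameter because duration surveys differ in whether
min/h refers to awake time — reproducing a specific study's doses may
require that study's convention. RfDs are consumed from a user CSV
(experimental or QSAR-predicted, recorded as provenance only); the
HQ > 1 concern threshold is configurable. Screening emits one record per
row × scenario, keeps RfD-less rows flagged rather than dropping them,
and classifies each (row, age group) as `concern` (average-scenario
exceedance), `upper_bound_only` (99th-percentile exceedance only), or
`none`.

## Problem sizes

The default test-suite and acceptance-script workloads use the
437-observation synthetic emulation, 1000-point random grids for oracle
equivalence, 200–300-draw property sweeps, and a 20-seed × 500-observation
recovery experiment — sizes chosen to exercise every code path and give
stable statistics while keeping a full run in the low seconds on one
core.

## Known limitations

* Organic, non-volatile leachables only; no metals, no scraped-particle
  or hand-to-mouth pathways, no textiles or coated surfaces.
* Predictions inherit the QSPR coefficients' quality; the shipped
  defaults are representative stand-ins (above).
* No temperature, saliva-composition or pH dependence.
* The regression model is only as transportable as its training domain;
  for chemical–material combinations outside it, the mechanistic model
  is the recommended predictor (it fits nothing and is linear in `C0`).
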