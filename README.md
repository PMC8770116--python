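# migrisk

Predicting chemical migration from children's-product materials into
saliva, and screening the resulting mouthing exposure for health risk.

Children mouth pacifiers, teethers, dolls and toys, and chemical
additives that are not covalently bound to the polymer (plasticizers,
flame retardants, parabens, fragrance allergens, ...) can migrate into
saliva during mouthing. Measured migration rates exist for only a few
dozen chemical–material combinations; `migrisk` closes that gap with two
predictive models that need only the chemical's molar mass *MW*, its
octanol–water partition coefficient *K*ow, the product material, and the
formulation concentration *C*₀ — making high-throughput screening of
whole product inventories possible. The intended users are exposure
scientists, risk assessors, and product designers comparing chemical
alternatives.

## Models

**Mechanistic material–saliva migration model.** The mouthed product is a
one-sided slab in contact with a finite saliva volume — the same physics
as chemical migration from food-contact packaging into liquid food.
Before the deviation time the migrated fraction follows the Fickian
short-term solution

    f_ts = (2/d_p) · √(D_p · t / π),

and afterwards a two-exponential relaxation carries it to the
partition-limited equilibrium α/(1+α), where α = (1/K_pf)·(V_f/V_p) is
the saliva-side capacity ratio. The deviation time t_dev scales as
d_p²/D_p with an empirical α-dependent prefactor, and the exponential
weights A, B, C are clamped power laws of α. The fraction converts to a
migration rate via R_mgr = f_mgr·m₀/(A_contact·t) in µg/10 cm²/min. The
two chemical-in-material inputs come from QSPRs: log₁₀ D_p linear in
*MW* per material, and log₁₀ K_ms linear in log₁₀ *K*ow and in the
ethanol-equivalency of the medium (20 % for quiescent in-vitro saliva,
50 % for in-vivo/agitated conditions or as a conservative choice).

**Regression-based model.** A multiple linear regression on log scale,
built by forward selection from candidates {log₁₀ C₀, log₁₀ D_p,
log₁₀ K_ow, log₁₀ K_ms, log₁₀ MW}. The shipped default is

    log₁₀ R_mgr = 3.23 + 0.73·log₁₀ D_p + 0.92·log₁₀ C₀ − 0.06·log₁₀ K_ow.

**Exposure and risk.** A rate becomes a daily dose through a mouthing
scenario (age group, body weight, day-averaged mouthing duration,
pacifier vs doll), E = Δt·(A_contact/10 cm²)·R_mgr/BW in µg/kg_BW/d, and a
hazard quotient HQ = E/RfD against the chemical's oral reference dose;
HQ > 1 flags a combination of concern.

Note: the QSPR coefficient file shipped in `migrisk/data/materials.yaml`
contains constructed representative defaults (see the file header and
`docs/methods.md`); swap in coefficients from your preferred published
QSPR source for quantitative work — no code change needed.

## Worked example

```python
import migrisk as m

lib = m.default_material_library()
arch = m.default_archetypes()

chem = m.ChemicalRecord(name="DEHP", cas="117-81-7", mw=390.6, log_kow=7.6,
                        group="phthalates and alternative plasticizers")
pvc = lib.get("PVC")
medium = m.MediumSpec(etoh_eq=m.select_etoh_eq(m.MediumSpec(agitation=True)),
                      agitation=True)

dp = m.estimate_dp(chem, pvc)
kms = m.estimate_kms(chem, pvc, medium)
print(f"D_p  = {float(dp):.3e} cm2/s")
print(f"K_ms = {float(kms):.3e}")

geom = arch["doll"].geometry
inputs = m.MechanisticInputs(d_p_coeff=float(dp), k_pf=float(kms),
                             geometry=geom, c0=250_000.0, duration=30 * 60)
result = m.migrated_fraction(inputs)
rate = m.migration_rate(result, inputs, pvc.density)
print(f"regime = {result.regime.value}, f_mgr = {result.f_mgr:.3e}")
print(f"R_mgr  = {rate:.3f} ug/10cm2/min")

scenario = [s for s in m.builtin_scenarios()
            if s.age_group.value == "3_to_6_months" and s.percentile.value == "p99"][0]
dose = m.daily_exposure(rate, scenario, "doll")
hq = m.hazard_quotient(dose, rfd=20.0)
print(f"E_mouthing = {dose.e_mouthing:.2f} ug/kg_BW/d, HQ = {hq.hq:.2f}")
```

prints

```
D_p  = 3.926e-11 cm2/s
K_ms = 1.995e+03
regime = saturation, f_mgr = 7.164e-06
R_mgr  = 0.155 ug/10cm2/min
E_mouthing = 1.26 ug/kg_BW/d, HQ = 0.06
```

DEHP at 25 % w/w in a PVC doll mouthed 30 min under agitated test
conditions: diffusion has already left the short-term regime
(`saturation`), about 7×10⁻⁶ of the chemical under the mouthed area has
migrated, giving 0.155 µg/10 cm²/min. For a 3–6-month-old in the
99th-percentile mouthing scenario that is 1.26 µg/kg_BW/d — 6 % of a
20 µg/kg/d reference dose, so below the HQ = 1 concern threshold.

## Command line

```sh
migrisk synth --n 437 --seed 1 --noise-sd 0.79 --out runs/ds.csv   # synthetic dataset
migrisk predict runs/ds.csv --out runs/pred.csv                    # per-row rates
migrisk fit runs/ds.csv --out runs/model.json                      # forward selection
migrisk validate runs/ds.csv --scheme kfold_random_10 --seed 1 --out runs/cv.json
migrisk risk runs/ds.csv --rfd rfd.csv --out runs/risk.csv         # HQ screening
```

Every run writes a `manifest.json` (version, seed, input hashes,
warning counts) beside its outputs.

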