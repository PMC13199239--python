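# nirapbpk

Whole-body physiologically based pharmacokinetic (PBPK) modeling of
**niraparib** — an orally dosed, weakly basic PARP inhibitor cleared by
carboxylesterase-1 (CES1) intracellular metabolism and renal excretion —
with likelihood-free (ABC-SMC) parameter calibration, hepatic-impairment
clearance scaling, model-based dose adjustment, and local sensitivity
analysis of steady-state tissue exposure.

The package is aimed at quantitative pharmacologists who want to
reproduce, probe or extend a mechanistic account of niraparib exposure
in special populations: which tissues accumulate the drug (bone marrow
as the hematological-toxicity site, gonads as an ovarian-cancer effect
compartment), how exposure rises with liver dysfunction, and what dose
preserves normal-function exposure in impaired patients.

## The model in brief

* **Absorption** — Weibull capsule dissolution
  (`f(t) = 1 − 2^(−(t/t50)²)`, t50 = 0.5 h), gastric emptying, a single
  small-intestine transit segment, permeability-limited uptake
  (`P_int·A_eff`) into a mucosal layer with gut-wall CES1 first pass,
  draining into the portal vein.
* **Distribution** — 15 organs × (vascular, interstitial,
  intracellular); perfusion-limited vascular↔interstitial exchange;
  charge-dependent interstitial↔intracellular permeability
  `P_eff = P0·[fn(pH) + κ(1−fn(pH))]` with
  `fn = 1/(1+10^(pKa−pH))`, which traps the base in acidic cell
  interiors (intracellular:interstitial unbound ratio ≈ 2.3–2.5 at
  pH 7.4→7.0 for pKa 9.087).
* **Elimination** — first-order CES1 metabolism of intracellular
  unbound drug (`CL_spec·[CES1]·C_ic,u·V_ic`; CES1 in liver, gut,
  kidney, heart, lung) plus renal clearance of kidney plasma
  (`CL_ren·BW`).
* **Hepatic impairment** — empirical power law
  `CL_spec(TBIL) = CL_spec,median·(TBIL/6.8 µM)^(−0.316)` over the
  NCI-ODWG severity groups, cross-checked by a mechanistic Child-Pugh
  physiology pathway.
* **Calibration** — ABC-SMC with a mean squared log-ratio objective,
  joint acceptance across dose cohorts, a multivariate-normal
  perturbation kernel, and a ±40% urinary mass-balance rejection
  window; two-stage workflow (five parameters, then P_int/CL_ren/pKa
  with logP and CL_spec fixed at posterior medians).

Everything in the system is first order, so the ODE system is linear in
amounts; the integrator exploits that for speed (one stiff solve per
dose plus matrix-exponential propagation).  See `docs/methods.md` for
the full account.

## Worked example

```python
import nirapbpk as npk
from nirapbpk.engine import DoseRegimen, PBPKModel, pk_metrics, urinary_unchanged_fraction

drug = npk.load_drug()                      # calibrated niraparib parameters
ind = npk.load_reference_individual()       # European adult female, 65 kg
form = npk.load_formulation()               # capsule, Weibull dissolution

model = PBPKModel(drug, ind, form)
res = model.simulate(DoseRegimen.qd(300.0, 28), dense_windows_h=[(648.0, 672.0)])

m = pk_metrics(res, "plasma", (648.0, 672.0))
print(f"plasma AUC_ss : {m.auc:8.1f} uM*min")
print(f"plasma Cmax   : {m.cmax:8.2f} uM  (Tmax {m.tmax_h - 648.0:.1f} h post dose)")
print(f"urine fraction: {urinary_unchanged_fraction(res):8.3f} of dose")
for organ in ("bone", "gonads"):
    auc = res.auc_intracellular_unbound(organ, (648.0, 672.0))
    print(f"{organ:6s} intracellular unbound AUC_ss: {auc:8.1f} uM*min")
```

prints

```
plasma AUC_ss :   4155.0 uM*min
plasma Cmax   :     4.52 uM  (Tmax 3.1 h post dose)
urine fraction:    0.100 of dose
bone   intracellular unbound AUC_ss:   1658.4 uM*min
gonads intracellular unbound AUC_ss:   1658.4 uM*min
```

i.e. at steady state under 300 mg once daily in a patient with normal
hepatic function, the model predicts a 24-h plasma exposure of
4155 µM·min with a 4.5 µM peak ~3 h after dosing, ~10% of the dose
excreted unchanged in urine, and near-identical intracellular unbound
exposure in bone and gonads (the pH ion-trap roughly doubles unbound
drug inside cells relative to interstitium, and both tissues share the
same pH gradient) — the toxicity:efficacy exposure ratio the dose
adjustments are meant to preserve.

Dose adjustment across hepatic-impairment groups:

```python
from nirapbpk.dosing import exposure_grid, select_dose

table = exposure_grid(None, None, drug, ind, form)   # 5 groups x 100..300 mg
for rec in select_dose(table, rule="harmonized-severe"):
    print(rec.group, rec.dose_mg)
# NHF 300.0 / mild 250.0 / MHI 200.0 / severe60 150.0 / severe120 150.0
```

## Command line

The same stages are scriptable via the `nirapbpk` console entry point:
`generate` (synthetic cohort bundles), `simulate`, `calibrate`
(two-stage ABC-SMC), `hepatic`, `adjust-dose`, `sensitivity`, and
`report` (assembles on-disk artifacts).  Each command writes CSV/JSON
artifacts plus a manifest with the configuration hash and seeds.

```bash
nirapbpk simulate --dose 300 --days 28 --out out/sim
nirapbpk adjust-dose --rule harmonized-severe --out out/dose
```

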