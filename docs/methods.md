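# Methods

`nirapbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) analysis of niraparib, an orally dosed PARP inhibitor that is a
weak base (pKa ≈ 9.1), cleared by carboxylesterase-1 (CES1) mediated
intracellular metabolism and renal excretion.  This note records the
model, its assumptions, the parameters that matter, the numerical
scheme, and what the synthetic-data pipeline does and does not
demonstrate.

## Model structure

**Gastrointestinal tract.** A capsule dose dissolves in the gastric
lumen following a Weibull profile, `f(t) = 1 − 2^(−(t/t50)^s)` with
time-to-50%-dissolved `t50 = 30 min` and shape `s = 2` (the
time-to-63.2% convention is available behind `convention="t63"`).
Dissolved and undissolved material empty from the stomach with
first-order kinetics (half-life 15 min, fasted) into a single
small-intestine segment with a 3.3 h transit time; unabsorbed drug
exits to feces.  Absorption is a unidirectional permeability-limited
flux, `P_int × A_eff`, from the lumen into a thin mucosal enterocyte
layer (0.30 L) where intestinal CES1 takes a gut-wall first pass; drug
escaping across the basolateral side joins the portal venous inflow of
the liver.  The mucosal escape route is modelled as weakly
charge-selective (local ionic permeability factor 0.2, versus ~1e−3
systemically) because the gut epithelium presents paracellular shunt
and carrier pathways absent from plain lipid bilayers; its small
effective exchange area (84 dm²/L) yields a ~10% first-pass extraction
of the absorbed dose at normal hepatic function, falling as CES1
activity falls.  Only the product `P_int × A_eff` is identifiable, which
is why `P_int` is the calibrated quantity and `A_eff` (34 dm²) is fixed
configuration.

**Distribution.** Fifteen organs (lung, heart, brain, muscle, bone,
gonads, kidney, liver, small intestine, stomach, skin, adipose, spleen,
pancreas, rest) are each split into vascular (plasma), interstitial and
intracellular sub-compartments.  Organs are perfused in parallel from
arterial plasma; the splanchnic organs drain through the portal vein
into the liver; the lung carries the full cardiac output in series on
the venous return.  The blood:plasma ratio is fixed at 1, so all flows
and clearances are plasma quantities.  Vascular–interstitial exchange is
fast (20 × organ plasma flow, acting on unbound drug), making the model
effectively perfusion-limited at that barrier; at steady state the
interstitial unbound concentration equals the local plasma unbound
concentration.

**Charge-dependent cellular exchange (ion trapping).**
Interstitial–intracellular exchange uses an effective permeability that
weights the neutral-species permeability by the Henderson–Hasselbalch
neutral fraction at the donor-side pH, plus a small
`ionic_permeability_factor` (κ) times the charged fraction:

    P_eff(pH) = P0 · [fn(pH) + κ · (1 − fn(pH))],   fn = 1/(1 + 10^(pKa−pH))

With interstitial pH 7.4 and intracellular pH 7.0 this traps the base
inside cells: at κ = 0 the steady-state intracellular:interstitial
unbound ratio is the closed form `(1+10^(pKa−7.0))/(1+10^(pKa−7.4))`
= 2.48 for pKa 9.087.  The shipped κ = 8e−4 gives a ratio of ~2.33,
the value required for the model's steady-state bone and gonads
intracellular unbound exposures to be mutually consistent with the
anchored plasma exposure (see "Calibrated constants" below).  κ > 0 is
also what makes the pKa dependence of tissue exposure non-monotone: the
trap ratio rises with pKa while the neutral fraction dominates, then
collapses toward 1 once both donor-side effective permeabilities are
κ-dominated — producing an interior maximum of intracellular exposure
near the drug's actual pKa in acid-inside tissues (bone, gonads,
muscle), and maxima shifted along the pKa axis in organs given
different intracellular pH (heart 7.1, kidney 7.2, lung 6.8).

**Intracellular binding.** Total:unbound concentration inside cells
follows a composition-based (tissue water / neutral lipid /
phospholipid / protein) partitioning scheme in the spirit of
composition-based prediction methods: neutral-lipid affinity scales
with the octanol:water coefficient (charged species ×1e−3),
phospholipid-membrane affinity follows `log10 K_mem = logP + 0.135`
with cations retaining 90% of the neutral affinity (headgroup
electrostatics), protein affinity is a small constant.  Binding affects
distribution kinetics and total tissue concentrations but not
steady-state unbound AUCs.

**Elimination.** CES1 metabolism is first order in intracellular
unbound concentration: flux = `CL_spec × [CES1]_organ × C_ic,u × V_ic`.
CES1 is present in liver (reference concentration, anchored), small
intestine, kidney, heart and lung with relative abundances normalized
to liver = 1 (0.031 / 0.012 / 0.0033 / 0.0065), from published
organ-abundance profiling.  First-order kinetics is justified by
dose-proportional clinical PK up to 400 mg — intracellular unbound
concentrations (~1–2 µM) sit well below any plausible Km.  Renal
clearance acts on total plasma concentration in the kidney vascular
space, `CL_ren × BW` (an unbound-based variant is available behind
`renal_on_unbound`).

## Drug parameters

| Parameter | Value | Units | Role |
|---|---|---|---|
| MW | 320.4 | g/mol | dose conversion mg→µmol |
| fu | 0.17 | – | plasma unbound fraction |
| logP | 2.997 | – | lipophilicity → binding, permeability |
| pKa | 9.087 | – | base ionization → ion trapping |
| P_int | 6.224e−5 | dm/min | intestinal permeability |
| CL_ren | 3.757e−4 | L/min/kg | renal plasma clearance |
| CL_spec | 7.49e−3 | L/min/µmol | CES1-normalized metabolic clearance |
| κ (ionic permeability) | 8e−4 | – | charged:neutral permeability ratio |

Internal units are µmol, L, min; interfaces use hours and µM, AUC in
µM·min.

## Calibrated constants and the enzyme-scale anchor

The paper-facing drug parameters above are data.  Four physiological
constants that the underlying platform treats as built-in defaults are
not printed anywhere and were fixed once during model development so
that the assembled model reproduces the published steady-state exposure
metrics of the 300 mg QD reference simulation; they are configuration,
not tunable knobs:

* **CES1 reference concentration** (50.51 µmol per L liver
  intracellular volume).  Only `CL_spec × [CES1]` is identifiable, so
  the absolute enzyme scale is anchored by root-finding the value at
  which the normal-hepatic-function 300 mg QD steady-state plasma AUC
  (24 h after the 28th dose) equals the model's published baseline of
  4155 µM·min.  `nirapbpk.anchoring.anchor_ces1_reference` re-derives
  it at run time; the YAML ships the result for convenience.
* **Ionic permeability factor** κ = 8e−4, set by the requirement that
  the steady-state intracellular unbound exposures of the poorly
  perfused reference tissues (bone, gonads) match the anchored plasma
  exposure through the ion-trap ratio (≈2.33× the interstitial unbound
  AUC).
* **Membrane-affinity intercept** 0.135 (log10), setting the volume of
  distribution and hence the peak:average concentration ratio of the
  daily profile.
* **Liver cellular exchange surface density** 3e5 dm²/L: hepatocyte
  sinusoidal membranes are heavily folded and hepatic uptake of
  lipophilic bases is not rate-limiting in vivo; operationally this
  keeps hepatic clearance proportional to `CL_spec`, which the observed
  exposure ratios across hepatic-impairment groups require.

## Hepatic impairment

**Empirical pathway (NCI-ODWG).**  `CL_spec(TBIL) = CL_spec,median ×
(TBIL/TBIL_median)^(−α)` with TBIL_median = 6.8 µM (normal hepatic
function) and α = 0.316, the exponent implied by the CL_spec ratio
calibrated on single-dose moderate-impairment data (`solve_alpha` is
the exact inverse of the power law; `calibrate_mhi_clspec` re-derives
the ratio from a synthetic MHI cohort).  Severity groups are
parameterized by median TBIL: 6.8 (NHF), 21.25 (mild), 41.9 (MHI),
60 (severe60), 120 (severe120) µM.  Only CL_spec changes — all CES1
pools scale together; volumes, flows and fu stay at normal values.

**Mechanistic pathway (Child-Pugh).**  Grade-specific multipliers on
functional liver volume, hepatic arterial and portal flows, renal flow
and unbound fraction, shipped as literature-style approximations in
`data/child_pugh.yaml` (the exact values used by the original analysis
are not published; ours are marked approximate and fully overridable).
An optional 3.3-fold hepatic CES1 reduction represents end-stage liver
disease.  The package asserts only the qualitative behaviour of this
pathway (exposure ordered A < B < C, CES1 reduction increasing CP-C
exposure); its quantitative outputs depend on the unpublished
multiplier tables.

## Dose adjustment

Steady-state exposures (plasma total AUC and Cmax; intracellular
unbound AUC in liver, kidney, bone, gonads, muscle, heart, lung, brain,
small intestine) are computed per group over doses 100–300 mg in 50 mg
steps.  Because every process is first order the model is exactly
linear in dose; the grid is filled by proportional scaling of one
simulation per group (a property the test suite verifies to 1e−6).
Selection rules:

* `plasma-max` — largest grid dose whose plasma AUC ratio vs the
  NHF/300 mg reference lies within ±20%; yields 250/200/200/150 mg.
* `harmonized-severe` — as above, but both severe groups share the
  lower of their admissible doses; yields 250/200/150/150 mg, matching
  clinical practice of one dose for all severe patients.
* `all-compartments` — every monitored tissue must also stay within
  the window.

The severe60 group admits 200 mg under the plasma-only criterion; the
choice between the two conventions is left to the caller because the
published selection rule for the severe categories is under-determined.

## Calibration (ABC-SMC)

Discrepancy: mean squared log-ratio, `ρ = (1/m) Σ ln²(y_j/y_obs,j)`,
symmetric and scale-balanced between high and low concentrations.
Priors are normal: logP mean 2.45 and pKa mean 10 (theoretical
estimates) with CV 20%; P_int, CL_ren, CL_spec centred on nominal
values with CV 100%.  Proposals violating positivity (or pKa ∉ (0,14))
are redrawn.  Generation 0 samples the priors; generation t fits a
multivariate-normal kernel (mean + covariance, Cholesky-regularized
with escalating diagonal jitter from 1e−10 if needed) to the previous
accepted set.  Acceptance demands ρ < ε_t for **every** cohort
simultaneously, plus a urinary mass-balance window: the predicted
unchanged-in-urine fraction of the dose must lie within ±40% (relative)
of the expected value.  ε follows a quantile rule (by default the median of the
previous generation's accepted max-over-cohort discrepancies), starting
at ∞ and strictly decreasing; a run aborts with diagnostics if the
acceptance rate falls below 1%.  Desk-scale recovery runs use a faster
quantile (0.25–0.3): with the median rule and few generations ε stalls
well above the observation-noise floor, in a regime where intestinal
permeability and metabolic clearance compensate along a ridge; the
ridge resolves once ε approaches a few times the noise floor.  Plain rejection is used (no importance
weights), matching the description level of the procedure being
reimplemented.  The two-stage workflow calibrates all five parameters,
fixes logP and CL_spec at their posterior medians, and re-calibrates
P_int, CL_ren and pKa, reducing posterior cross-correlation.  The
default population size, 328, matches the final posterior set used for
credible-band simulation; desk-scale runs use 100–200 particles and 3–4
generations.  Calibration simulations use rtol 1e−6 (vs 1e−8 for
reporting runs); the discrepancy differences this introduces are far
below the accepted thresholds.

## Synthetic data

No patient-level or machine-readable clinical data exist for this
analysis — the original inputs were cohort means digitized from
literature plots.  The generator therefore emulates exactly that
structure: the packaged ("truth") model is simulated, sampled on a
sparse schedule (0.25–24 h on day 1, peak and trough on day 21 for
repeated dosing), and perturbed with i.i.d. multiplicative lognormal
noise with log-mean 0 and CV chosen per scenario (default 15%;
parameter-recovery runs use 10%, the level at which the sparse designs
keep the weakly identified absorption parameter within its recovery
tolerance).  The urinary observation is the truth model's own unchanged
fraction (~0.10 of the dose) with the ±40% window.  Scenarios:
`calibration_210qd`, `multi_dose_60_80_210`, `mhi_single_300` (truth
CL_spec × 0.563, the power-law value at TBIL 41.9 µM), and
`validation_300sd_300qd_200qd`.

What passing recovery tests show: the calibration machinery is
internally consistent — data generated by the engine, with the assumed
noise law and the urine constraint, return the generating parameters.
What they do not show: that the model or priors are adequate for real
digitized cohorts, which carry between-study variability, digitization
error and correlated residuals that the generator deliberately omits.

## Numerical scheme

All processes are first order, so the state equation is `y' = M y`
within a dosing interval, except the Weibull dissolution hazard, which
is the only time-varying coefficient.  The integrator exploits this:
for each dose, the response to the dose alone is computed once by a
stiff BDF solve (analytic Jacobian) over a "forcing window" of 8 h —
by which time the remaining undissolved fraction is ~2^−256 and is
folded into the dissolved pool — and the remainder of every interval is
propagated exactly with a cached `expm(M Δt)`.  Intervals containing
requested output samples are integrated densely instead.  Tolerances:
rtol 1e−8, atol 1e−10 µmol (defaults).  AUCs are computed by
cumulative-integral states inside the ODE system (solver-consistent,
not post-hoc trapezoids); Cmax/Tmax come from 1-min dense sampling of
the final interval.  Mass balance (administered = in-body + eliminated
+ fecal loss) holds to ~1e−11 relative; the test suite enforces 1e−6.
Steady-state questions (constant-rate infusion) are answered exactly by
solving the linear balance `M_dyn y = −u` instead of time stepping.

Degenerate inputs: negative states beyond tolerance and non-convergent
solves raise `IntegrationError`; empty metric windows and non-positive
concentrations in the discrepancy raise `ValueError`.

## Known limitations

* Organ volumes, flows, compositions and Child-Pugh multipliers are
  literature-style approximations of unpublished platform defaults;
  absolute tissue exposures inherit that uncertainty even where plasma
  metrics are anchored.
* No P-gp transport (implicitly absorbed into effective P_int and
  CL_ren), no Michaelis–Menten saturation, no enterohepatic
  recirculation, no between-study variability, no inter-individual
  variability population layer.
* The bone compartment is a single homogeneous tissue; red-marrow
  sub-tissue exposure is not resolved separately.
* The empirical TBIL power law extrapolates beyond the moderate
  impairment data that determine α; severe-impairment predictions are
  model-based extrapolation, cross-checked only qualitatively by the
  Child-Pugh pathway.
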