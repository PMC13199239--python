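# Reference European adult female for whole-body PBPK simulation.
#
# Volumes in L, plasma flows in L/min, pH in pH units.  Organ volumes,
# plasma flows and sub-compartment fractions are literature approximations
# in the style of ICRP-89 reference tables, expressed on a plasma basis
# (blood:plasma ratio fixed at 1).  Tissue composition fractions (water,
# neutral lipid, phospholipid, protein per tissue volume) follow published
# tissue-composition compilations used by tissue-partitioning methods.
# CES1 relative abundances are normalized to liver = 1 and are non-zero
# only in liver, small intestine, kidney, heart and lung.
body_weight: 65.0
cardiac_output: 3.0          # plasma flow through the lung, L/min
plasma_pH: 7.4
arterial_plasma_volume: 0.65
venous_plasma_volume: 1.35
gastric_emptying_halflife: 15.0    # min, fasted
small_intestine_transit_time: 198.0  # min (3.3 h)
lumen_volume: 0.105                # L, effective small-intestine fluid
intestinal_surface_area: 34.0      # dm^2, effective absorptive area
cell_surface_area_per_volume: 2000.0  # dm^2 per L intracellular volume
# umol CES1 per L liver intracellular volume.  This absolute abundance
# anchor is not directly measurable; the shipped value is the result of
# anchoring the calibrated model so that the normal-hepatic-function
# 300 mg QD steady-state plasma AUC equals 4155 uM*min (see
# nirapbpk.anchoring, which re-derives it at run time).
ces1_reference_concentration: 50.5062
portal_organs: [stomach, small_intestine, spleen, pancreas]
fu_scale: 1.0
# absorptive mucosal layer (gut-wall first-pass): small volume, weakly
# charge-selective basolateral escape (paracellular shunt / carrier
# traffic); together these give a ~10% first-pass extraction of the
# absorbed dose by intestinal CES1
mucosa_volume: 0.30
mucosa_surface_area_per_volume: 84.0
mucosa_ionic_permeability_factor: 0.2
organs:
  lung:
    total_volume: 0.95
    plasma_fraction: 0.18
    interstitial_fraction: 0.19
    intracellular_fraction: 0.55
    blood_flow: 3.0
    composition: {water: 0.79, neutral_lipid: 0.022, phospholipid: 0.014, protein: 0.13}
    pH_interstitial: 7.4
    pH_intracellular: 6.8
    ces1_relative_abundance: 0.0065
  heart:
    total_volume: 0.25
    plasma_fraction: 0.10
    interstitial_fraction: 0.14
    intracellular_fraction: 0.70
    blood_flow: 0.12
    composition: {water: 0.76, neutral_lipid: 0.014, phospholipid: 0.011, protein: 0.16}
    pH_interstitial: 7.4
    pH_intracellular: 7.1
    ces1_relative_abundance: 0.0033
  brain:
    total_volume: 1.30
    plasma_fraction: 0.03
    interstitial_fraction: 0.18
    intracellular_fraction: 0.75
    blood_flow: 0.36
    composition: {water: 0.77, neutral_lipid: 0.051, phospholipid: 0.0565, protein: 0.08}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  muscle:
    total_volume: 17.5
    plasma_fraction: 0.02
    interstitial_fraction: 0.13
    intracellular_fraction: 0.80
    blood_flow: 0.36
    composition: {water: 0.76, neutral_lipid: 0.022, phospholipid: 0.0072, protein: 0.17}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  bone:
    total_volume: 7.8
    plasma_fraction: 0.04
    interstitial_fraction: 0.10
    intracellular_fraction: 0.50
    blood_flow: 0.15
    composition: {water: 0.45, neutral_lipid: 0.074, phospholipid: 0.0011, protein: 0.20}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  gonads:
    total_volume: 0.011
    plasma_fraction: 0.07
    interstitial_fraction: 0.20
    intracellular_fraction: 0.70
    blood_flow: 0.0005
    composition: {water: 0.80, neutral_lipid: 0.007, phospholipid: 0.012, protein: 0.15}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  kidney:
    total_volume: 0.275
    plasma_fraction: 0.11
    interstitial_fraction: 0.20
    intracellular_fraction: 0.65
    blood_flow: 0.51
    composition: {water: 0.78, neutral_lipid: 0.021, phospholipid: 0.016, protein: 0.15}
    pH_interstitial: 7.4
    pH_intracellular: 7.2
    ces1_relative_abundance: 0.012
  liver:
    total_volume: 1.40
    plasma_fraction: 0.10
    interstitial_fraction: 0.16
    intracellular_fraction: 0.70
    blood_flow: 0.195          # hepatic artery; portal inflow adds on top
    composition: {water: 0.75, neutral_lipid: 0.035, phospholipid: 0.025, protein: 0.18}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 1.0
    # hepatocyte sinusoidal membrane is heavily folded; hepatocellular
    # uptake of lipophilic bases is not rate-limiting
    cell_surface_area_per_volume: 300000.0
  small_intestine:
    total_volume: 0.60
    plasma_fraction: 0.08
    interstitial_fraction: 0.17
    intracellular_fraction: 0.70
    blood_flow: 0.30
    composition: {water: 0.75, neutral_lipid: 0.049, phospholipid: 0.016, protein: 0.15}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.031
  stomach:
    total_volume: 0.15
    plasma_fraction: 0.08
    interstitial_fraction: 0.17
    intracellular_fraction: 0.70
    blood_flow: 0.03
    composition: {water: 0.75, neutral_lipid: 0.049, phospholipid: 0.016, protein: 0.15}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  skin:
    total_volume: 2.30
    plasma_fraction: 0.03
    interstitial_fraction: 0.30
    intracellular_fraction: 0.60
    blood_flow: 0.15
    composition: {water: 0.65, neutral_lipid: 0.028, phospholipid: 0.011, protein: 0.25}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  adipose:
    total_volume: 22.0
    plasma_fraction: 0.01
    interstitial_fraction: 0.14
    intracellular_fraction: 0.80
    blood_flow: 0.255
    composition: {water: 0.15, neutral_lipid: 0.79, phospholipid: 0.002, protein: 0.05}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  spleen:
    total_volume: 0.13
    plasma_fraction: 0.22
    interstitial_fraction: 0.20
    intracellular_fraction: 0.55
    blood_flow: 0.09
    composition: {water: 0.78, neutral_lipid: 0.012, phospholipid: 0.014, protein: 0.15}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  pancreas:
    total_volume: 0.12
    plasma_fraction: 0.10
    interstitial_fraction: 0.17
    intracellular_fraction: 0.70
    blood_flow: 0.03
    composition: {water: 0.66, neutral_lipid: 0.041, phospholipid: 0.017, protein: 0.17}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
  rest:
    total_volume: 3.50
    plasma_fraction: 0.04
    interstitial_fraction: 0.16
    intracellular_fraction: 0.75
    blood_flow: 0.4495
    composition: {water: 0.75, neutral_lipid: 0.05, phospholipid: 0.01, protein: 0.15}
    pH_interstitial: 7.4
    pH_intracellular: 7.0
    ces1_relative_abundance: 0.0
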