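# Niraparib drug parameters (final calibrated values) and capsule formulation.
#
# Units: MW g/mol; P_int dm/min; CL_ren L/min/kg; CL_spec L/min/umol CES1;
# dissolution_time_50pct in minutes.  ionic_permeability_factor is the ratio
# of charged-to-neutral species membrane permeability used by the
# charge-dependent cellular exchange model; its default was fixed during
# model development so that predicted steady-state intracellular unbound
# exposures in poorly perfused reference tissues (bone, gonads) match the
# anchored plasma exposure (see docs/methods.md).
drug:
  mw: 320.4
  fu: 0.17
  logP: 2.997
  pKa: 9.087
  p_int: 6.224e-05
  cl_ren: 3.757e-04
  cl_spec: 7.49e-03
  ionic_permeability_factor: 8.0e-04
formulation:
  dissolution_time_50pct: 30.0
  dissolution_shape: 2.0
  form: capsule
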