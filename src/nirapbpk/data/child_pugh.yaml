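# Child-Pugh grade physiology multipliers, relative to the healthy reference.
#
# Literature-style approximations (Edginton/Johnson-type cirrhosis tables):
# functional liver volume shrinks, portal flow falls with portosystemic
# shunting while the hepatic artery partially compensates, renal plasma
# flow falls, the unbound fraction rises with hypoalbuminemia, and hepatic
# CES1 abundance declines.  All values are configuration, overridable per
# analysis; grade NONE is the identity.
A:
  liver_volume: 0.85
  hepatic_arterial_flow: 1.10
  portal_flow: 0.75
  renal_flow: 0.95
  fu_scale: 1.05
  ces1: 0.80
B:
  liver_volume: 0.70
  hepatic_arterial_flow: 1.20
  portal_flow: 0.55
  renal_flow: 0.85
  fu_scale: 1.12
  ces1: 0.60
C:
  liver_volume: 0.55
  hepatic_arterial_flow: 1.30
  portal_flow: 0.35
  renal_flow: 0.70
  fu_scale: 1.25
  ces1: 0.45
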