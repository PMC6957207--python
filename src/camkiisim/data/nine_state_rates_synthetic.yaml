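# Nine-state CaM kinetic parameters -- SYNTHETIC default set.
#
# Each CaM carries 0-2 Ca2+ on its N lobe and 0-2 on its C lobe (9 states;
# (0,0) is apo-CaM).  The CaMKII dissociation constants below are anchored to
# published equilibrium values where available:
#   K_D(CaM_2C-CaMKII)   = 7.4e-6 M      -> state (0, 2)
#   K_D(apoCaM-CaMKII)   = 1.45e-3 M     -> state (0, 0)
#   trapping factor 1000 (koff / 1000 on pThr-286 subunits), which moves the
#   apo-CaM K_D on phosphorylated subunits to 1.45e-6 M.
# The remaining per-state constants and all lobe kinetics are a SYNTHETIC
# interpolation constructed for this package: affinity increases
# monotonically with Ca2+ load (the C lobe contributing more than the N
# lobe), on-rates grow with Ca2+ load, and lobe on-rates are scaled so that
# Ca2+-CaM equilibration is fast relative to every stimulus timescale while
# staying tractable for event-driven simulation.  They are placeholders for
# a transcription of a measured 9-state network, not measurements.
#
# Units: kon in M^-1 s^-1, koff in s^-1.

trapping_factor: 1000.0
trap_all_states: true
autophos_rate: 1.0

# Ca2+ binding to free CaM, per lobe, sequential two-site (site 1 then 2).
ca_free:
  N:
    kon: [1.0e6, 1.0e6]
    koff: [30.0, 5.0]     # K_D 30 uM then 5 uM
  C:
    kon: [1.0e6, 1.0e6]
    koff: [10.0, 1.0]     # K_D 10 uM then 1 uM

# Ca2+ binding to CaMKII-bound CaM: same on-rates, 10-fold slower release
# (target-bound CaM holds its Ca2+ longer, which is what lets apo-CaM arise
# in place on the kinase after chelation).
ca_bound:
  N:
    kon: [1.0e6, 1.0e6]
    koff: [3.0, 0.5]
  C:
    kon: [1.0e6, 1.0e6]
    koff: [1.0, 0.1]

# CaM-CaMKII binding per CaM state (n_lobe_ca, c_lobe_ca).
camkii:
  "0,0": {kon: 1.0e5, koff: 145.0}     # K_D 1.45 mM  (anchor)
  "1,0": {kon: 2.0e5, koff: 100.0}     # K_D 0.5 mM
  "2,0": {kon: 5.0e5, koff: 50.0}      # K_D 0.1 mM
  "0,1": {kon: 5.0e5, koff: 50.0}      # K_D 0.1 mM
  "1,1": {kon: 1.0e6, koff: 50.0}      # K_D 50 uM
  "2,1": {kon: 2.0e6, koff: 40.0}      # K_D 20 uM
  "0,2": {kon: 1.0e6, koff: 7.4}       # K_D 7.4 uM  (anchor)
  "1,2": {kon: 5.0e6, koff: 5.0}       # K_D 1 uM
  "2,2": {kon: 1.0e7, koff: 0.1}       # K_D 10 nM
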