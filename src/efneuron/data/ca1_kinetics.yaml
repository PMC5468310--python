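# Channel kinetics and passive constants for the CA1-pyramidal-like model.
#
# Version-controlled parameter file: everything electrophysiological that is
# not geometry lives here, never in code. Densities are peak conductances in
# pS/um^2; a channel with a nonzero slope increases linearly with path
# distance from the soma midpoint (per 100 um) on the section kinds listed
# under slope_applies_to, and uses its somatic density elsewhere.
#
# The gating schemes are this package's transcription of the classic
# hippocampal CA1 channel set (transient Na+, slow delayed-rectifier K+,
# fast A-type K+ with proximal-type voltage-dependent valence, and the
# hyperpolarization-activated cation current I_h), written in the rate-form
# algebra documented in efneuron.kinetics. Time-constant floors follow the
# same lineage; rates are evaluated at the stated temperature with no
# additional q10 scaling.
name: ca1-default
version: 1
temperature_c: 24.0

passive:
  cm_uF_per_cm2: 1.0
  ra_ohm_cm: 80.0
  rm_kohm_cm2: 28.0
  e_leak_mV: -65.0

reversal_potentials_mV:
  Na: 55.0
  K: -90.0
  h: -30.0

channels:
  Na:
    reversal: Na
    density:
      somatic_pS_per_um2: 200.0
      slope_pS_per_um2_per_100um: 0.0
      slope_applies_to: []
    gates:
      - name: m
        exponent: 3
        alpha: {form: trap, a: 0.4, vhalf: -30.0, k: 7.2}
        beta: {form: trap_neg, a: 0.124, vhalf: -30.0, k: 7.2}
        inf: {form: rate_ratio}
        tau: {form: inverse_rate_sum, min: 0.02}
      - name: h
        exponent: 1
        alpha: {form: trap, a: 0.03, vhalf: -45.0, k: 1.5}
        beta: {form: trap_neg, a: 0.01, vhalf: -45.0, k: 1.5}
        inf: {form: boltzmann, vhalf: -50.0, k: 4.0}
        tau: {form: inverse_rate_sum, min: 0.5}

  Kdr:
    reversal: K
    density:
      somatic_pS_per_um2: 100.0
      slope_pS_per_um2_per_100um: 0.0
      slope_applies_to: []
    gates:
      - name: n
        exponent: 1
        inf: {form: bg, vhalf: 13.0, zeta: -3.0}
        tau: {form: bg, vhalf: 13.0, zeta: -3.0, gm: 0.7, a0: 0.02, min: 1.0}

  Ka:
    reversal: K
    density:
      somatic_pS_per_um2: 250.0
      slope_pS_per_um2_per_100um: 250.0
      slope_applies_to: [dend_proximal, dend_distal]
    gates:
      - name: n
        exponent: 1
        inf: {form: bg, vhalf: 11.0, zeta: -1.5,
              zeta_mod: {pw: -1.0, tq: -40.0, qq: 5.0}}
        tau: {form: bg, vhalf: 11.0, zeta: -1.5, gm: 0.55, a0: 0.05, min: 0.1,
              zeta_mod: {pw: -1.0, tq: -40.0, qq: 5.0}}
      - name: l
        exponent: 1
        inf: {form: bg, vhalf: -56.0, zeta: 3.0}
        tau: {form: linear, slope: 0.26, v0: -50.0, min: 2.0}

  h:
    reversal: h
    density:
      somatic_pS_per_um2: 0.5
      slope_pS_per_um2_per_100um: 1.5
      slope_applies_to: [dend_proximal, dend_distal]
    gates:
      - name: l
        exponent: 1
        inf: {form: boltzmann, vhalf: -81.0, k: 8.0}
        tau: {form: bg, vhalf: -75.0, zeta: 2.2, gm: 0.4, a0: 0.011, min: 2.0}
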