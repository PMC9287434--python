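# Figure-scenario presets: fully specified, reproducible simulation
# configurations (compound, concentration in uM, bath/drug pH, protocol
# variant and overrides, calibration targets).
#
# Calibration blocks carry measured observables (fractions, seconds) that
# the membrane-path rates are solved against at run time; nothing fitted is
# stored here. MK-801 presets use the stepped protocol: a 20 s step to
# +30 mV during recovery is required for full unbinding of this slow,
# trapped blocker before the second control application, and the minimum
# search stops before the step (search_to_s).
fig1d_ph72:
  compound_name: memantine
  drug_uM: 100.0
  bath_pH: 7.2
  calibration: &mem_cal
    kind: min_tau
    conc_uM: 100.0
    true_min: 0.611
    tau_s: 0.0464
    bath_pH: 7.2
fig1_ph9jump:
  compound_name: memantine
  drug_uM: 100.0
  bath_pH: 7.2
  drug_pH: 9.0
  jump_normalization: true
  calibration: *mem_cal
fig2g_tmm:
  compound_name: tmm
  drug_uM: 1000.0
  bath_pH: 9.0
fig2g_dmm:
  compound_name: dmm
  drug_uM: 165.0
  bath_pH: 9.0
  calibration:
    kind: share          # structural memantine analog: same fenestration rates
    source: fig1d_ph72
fig4_mk801_1uM:
  compound_name: mk-801
  drug_uM: 1.0
  bath_pH: 7.2
  protocol_kind: reblock
  protocol_kwargs: &mk801_protocol
    n_steps: 1
    step_mV: 30.0
    step_ms: 20000.0
    step_start_s: 15.0
    glu2_s: 40.0
  calibration: &mk801_cal
    kind: tau_pair
    concs_uM: [1.0, 10.0]
    taus_s: [1.002, 0.311]
    bath_pH: 7.2
    protocol_kind: reblock
    search_to_s: 14.5
    protocol_kwargs: *mk801_protocol
fig4_mk801_10uM:
  compound_name: mk-801
  drug_uM: 10.0
  bath_pH: 7.2
  protocol_kind: reblock
  protocol_kwargs: *mk801_protocol
  calibration: *mk801_cal
fig4e_reblock:
  compound_name: memantine
  drug_uM: 100.0
  bath_pH: 7.2
  drug_pH: 9.0
  protocol_kind: reblock
  jump_normalization: true
  calibration: *mem_cal
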