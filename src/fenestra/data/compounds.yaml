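# NMDAR channel-blocker library.
#
# Units: pKa dimensionless; kon_aq per-uM per-s (aqueous deep-site
# association, charged form); koff0 per-s (deep-site dissociation at 0 mV);
# v_efold mV (e-fold depolarization of the unblock rate); k_in per-uM per-s
# (membrane entry of the uncharged form); k_out per-s (membrane exit;
# 1/k_out is the reservoir drain time constant); kon_mem per-reservoir-unit
# per-s (membrane-path deep-site association).
#
# pKa values are inputs, never computed (memantine 10.4 measured, DMM 10.7
# computed by its designers; the rest are nominal literature-style values).
# Rate constants are package defaults at a realistic order of magnitude;
# scenario calibration routines override kon_mem/koff0 from measured
# observables, so library kon_mem defaults to 0 (no membrane path until
# calibrated) except where a compound's phenotype fixes it.
memantine:
  charge_type: titratable_amine
  pKa: 10.4
  kon_aq: 46.0
  koff0: 67.0
  v_efold: 40.0
  k_in: 1.0
  k_out: 0.5      # ~2 s reservoir drain
  kon_mem: 0.0
dmm:
  charge_type: titratable_amine
  pKa: 10.7
  kon_aq: 4.6
  koff0: 67.0
  v_efold: 40.0
  k_in: 1.0
  k_out: 0.5
  kon_mem: 0.0
tmm:
  charge_type: permanent_cation   # quaternary ammonium: no uncharged form
  kon_aq: 1.1
  koff0: 67.0
  v_efold: 40.0
mk-801:
  charge_type: titratable_amine
  pKa: 8.37
  kon_aq: 80.0
  koff0: 3.8      # slow unbinder at rest
  v_efold: 40.0
  k_in: 1.0
  k_out: 0.1      # slow membrane exit; full recovery needs depolarization
  kon_mem: 0.0
pcp:
  charge_type: titratable_amine
  pKa: 8.5
  kon_aq: 30.0
  koff0: 20.0
  v_efold: 40.0
  k_in: 1.0
  k_out: 0.2
  kon_mem: 0.0
dextrorphan:
  charge_type: titratable_amine
  pKa: 9.2
  kon_aq: 10.0
  koff0: 30.0
  v_efold: 40.0
  k_in: 1.0
  k_out: 0.3
  kon_mem: 0.0
rl-208:
  charge_type: titratable_amine
  pKa: 10.1
  kon_aq: 10.0
  koff0: 30.0
  v_efold: 40.0
  k_in: 1.0
  k_out: 0.3
  kon_mem: 0.0
ketamine:
  charge_type: titratable_amine
  pKa: 7.5
  kon_aq: 30.0
  koff0: 30.0
  v_efold: 40.0
  k_in: 1.0
  k_out: 5.0      # placeholder: rapid membrane exit, no membrane path
  kon_mem: 0.0
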