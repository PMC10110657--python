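# Mouse physiology and retrorsine parameter defaults.
#
# Physiological constants follow standard rodent reference compilations;
# compound and hepatic constants are the package's packaged defaults for
# retrorsine (see docs/methods.md for provenance and calibration notes).
schema_version: 1
species: mouse
bodyweight_kg: 0.025
hematocrit: 0.45
gfr_ml_min_kg: 8.0
liver_mass_per_kg: 54.8
liver_fraction_cellular: 0.722

tissue_volumes_ml_per_kg:
  adipose: 70.0
  bone: 107.0
  brain: 16.5
  gut: 42.0
  gut_lumen: 30.0
  heart: 5.0
  kidneys: 16.7
  liver: 54.8
  lungs: 7.3
  muscle: 384.0
  skin: 165.0
  spleen: 3.5
  plasma: 49.0

tissue_flows_ml_min_kg:
  adipose: 30.0
  bone: 25.0
  brain: 15.0
  gut: 80.0
  heart: 35.0
  kidneys: 65.0
  lungs: 15.0
  muscle: 90.0
  skin: 30.0
  spleen: 5.92
  hepatic_artery: 30.0

ph:
  plasma: 7.4
  interstitial: 7.4
  intracellular: 7.0
  red_blood_cell: 7.22

compound:
  name: retrorsine
  molar_mass_g_mol: 351.44   # C18H25NO6
  logp: 1.18
  ionization:
    type: base
    pka: [8.2]
  fup: 0.600
  blood_to_plasma_ratio: 0.792
  fu_liv_c: 0.56
  fu_invitro: 1.0

absorption:
  k_per_per_h: 166.0     # peritoneal absorption, half-life 15 s
  k_a_per_h: 0.910       # intestinal absorption rate constant
  f_a: 0.783             # fraction absorbed, Caco-2 correlation

hepatic:
  cl_act_in_ml_min_g: 0.516
  cl_act_ef_ml_min_g: 0.0
  ps_diff_ml_min_g: 0.190
  cl_bile_ml_min_g: 0.0      # no biliary excretion assumed in mouse
  vmax_liv_nmol_min_g: 27.6
  km_liv_um: 55.4
  k_liv_int_u_vi: 0.355      # unbound interstitial : lumped-vi partition
  k_liv_vas_vi: 1.0          # vascular : lumped-vi partition

metabolites:
  f_dhr_gsh: 0.10
  f_dhr_prot: 0.05
  f_dhr_dna: 0.002
  f_other: 0.848
  lambda_dhr_gsh_per_h: 0.10
  lambda_dhr_prot_per_h: 0.02
  lambda1_dhr_dna_per_h: 0.06
  lambda2_dhr_dna_per_h: 0.004
  k_dhr_dna_per_h: 0.01
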