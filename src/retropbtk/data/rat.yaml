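# Rat physiology and retrorsine parameter defaults (see mouse.yaml / docs/methods.md).
schema_version: 1
species: rat
bodyweight_kg: 0.25
hematocrit: 0.45
gfr_ml_min_kg: 8.0
liver_mass_per_kg: 36.6
liver_fraction_cellular: 0.722

tissue_volumes_ml_per_kg:
  adipose: 70.0
  bone: 73.0
  brain: 5.7
  gut: 27.0
  gut_lumen: 30.0
  heart: 3.3
  kidneys: 7.3
  liver: 36.6
  lungs: 5.0
  muscle: 404.0
  skin: 190.0
  spleen: 2.0
  plasma: 40.0

tissue_flows_ml_min_kg:
  adipose: 20.0
  bone: 12.0
  brain: 5.0
  gut: 40.0
  heart: 15.0
  kidneys: 37.0
  lungs: 8.0
  muscle: 75.0
  skin: 15.0
  spleen: 3.29
  hepatic_artery: 15.0

ph:
  plasma: 7.4
  interstitial: 7.4
  intracellular: 7.0
  red_blood_cell: 7.22

compound:
  name: retrorsine
  molar_mass_g_mol: 351.44
  logp: 1.18
  ionization:
    type: base
    pka: [8.2]
  fup: 0.600
  blood_to_plasma_ratio: 0.792
  fu_liv_c: 0.56
  fu_invitro: 1.0

absorption:
  k_per_per_h: 166.0
  k_a_per_h: 0.910
  f_a: 0.783

hepatic:
  cl_act_in_ml_min_g: 0.887
  cl_act_ef_ml_min_g: 0.0
  ps_diff_ml_min_g: 0.394
  cl_bile_ml_min_g: 0.101
  vmax_liv_nmol_min_g: 91.7
  km_liv_um: 44.3
  k_liv_int_u_vi: 0.333
  k_liv_vas_vi: 1.0

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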