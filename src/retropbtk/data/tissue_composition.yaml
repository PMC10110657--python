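# Tissue constituent fractions for the Rodgers-Rowland mechanistic
# partition-coefficient model (rodent values; fractions of tissue volume).
#
# f_ew  extracellular water, f_iw intracellular water,
# f_nl  neutral lipid, f_np neutral phospholipid,
# ap_mg_g  acidic phospholipid content (mg/g tissue),
# pr_ratio tissue-to-plasma ratio of the binding protein (albumin-type,
#          used for neutrals/weak bases/acids only).
schema_version: 1
ph:
  plasma: 7.4
  intracellular: 7.0
  red_blood_cell: 7.22
plasma:
  f_nl: 0.0023
  f_np: 0.0013
red_blood_cell:
  f_iw: 0.603
  f_nl: 0.0017
  f_np: 0.0029
  ap_mg_g: 0.5
tissues:
  adipose:  {f_ew: 0.135, f_iw: 0.017, f_nl: 0.853,  f_np: 0.0016, ap_mg_g: 0.40, pr_ratio: 0.049}
  bone:     {f_ew: 0.100, f_iw: 0.346, f_nl: 0.017,  f_np: 0.0017, ap_mg_g: 0.67, pr_ratio: 0.100}
  brain:    {f_ew: 0.162, f_iw: 0.620, f_nl: 0.039,  f_np: 0.0015, ap_mg_g: 0.40, pr_ratio: 0.048}
  gut:      {f_ew: 0.282, f_iw: 0.475, f_nl: 0.038,  f_np: 0.0125, ap_mg_g: 2.41, pr_ratio: 0.158}
  heart:    {f_ew: 0.320, f_iw: 0.456, f_nl: 0.014,  f_np: 0.0111, ap_mg_g: 2.25, pr_ratio: 0.157}
  kidneys:  {f_ew: 0.273, f_iw: 0.483, f_nl: 0.012,  f_np: 0.0240, ap_mg_g: 5.03, pr_ratio: 0.130}
  liver:    {f_ew: 0.161, f_iw: 0.573, f_nl: 0.014,  f_np: 0.0240, ap_mg_g: 4.56, pr_ratio: 0.086}
  lungs:    {f_ew: 0.336, f_iw: 0.446, f_nl: 0.022,  f_np: 0.0128, ap_mg_g: 3.91, pr_ratio: 0.212}
  muscle:   {f_ew: 0.118, f_iw: 0.630, f_nl: 0.010,  f_np: 0.0072, ap_mg_g: 1.53, pr_ratio: 0.064}
  skin:     {f_ew: 0.382, f_iw: 0.291, f_nl: 0.060,  f_np: 0.0044, ap_mg_g: 1.32, pr_ratio: 0.277}
  spleen:   {f_ew: 0.207, f_iw: 0.579, f_nl: 0.0077, f_np: 0.0113, ap_mg_g: 3.18, pr_ratio: 0.097}
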