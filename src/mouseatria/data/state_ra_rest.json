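{
 "format": "mouseatria-state-v1",
 "digest": "9cdd22c41e85",
 "state": {
  "V": -85.13332197676749,
  "m_Na": 0.0015115002170892104,
  "h_Na": 0.9853443864724301,
  "j_Na": 0.9907523100344819,
  "mL": 0.000324617473074396,
  "hL": 0.41613696575393283,
  "x_ss": 0.006389602628220127,
  "ICaL_C2": 0.999956567271704,
  "ICaL_C1": 2.895722475481133e-07,
  "ICaL_O": 2.765776076324111e-07,
  "ICaL_IV1": 2.3765082584449984e-05,
  "ICaL_IV2": 1.6430345611079642e-05,
  "ICaL_ICa": 2.517178607279174e-06,
  "ICaL_ICaV": 1.5397185762910845e-07,
  "Ito_C3": 0.9344393160596176,
  "Ito_C2": 0.06382236439963705,
  "Ito_C1": 0.0014530263036028998,
  "Ito_O": 1.1026891128468523e-05,
  "Ito_If": 3.681835297153549e-06,
  "Ito_Is": 8.260153893024507e-07,
  "Ito_CI": 0.0002697584955441218,
  "IKur_C1": 0.9453963214640249,
  "IKur_C2": 0.05345934211462658,
  "IKur_C3": 0.0011336123790401497,
  "IKur_C4": 1.0683733757464046e-05,
  "IKur_O": 3.7758798177699144e-08,
  "IKur_I": 2.549333234267803e-09,
  "IKr_C1": 0.9109991070101167,
  "IKr_C2": 0.019115416708864418,
  "IKr_C3": 0.06951404044179921,
  "IKr_O": 0.00031530624847589053,
  "IKr_I": 5.612959072324419e-05,
  "RyR_R": 0.8511550720460076,
  "RyR_O": 1.3183339545590753e-06,
  "RyR_I": 2.3053916589576322e-07,
  "RyR_RI": 0.14884337908077303,
  "Na_i": 10.618630178886418,
  "K_i": 139.6463436873222,
  "Cl_i": 7.4630271835756465,
  "Ca_i": 0.00010301070322401456,
  "Ca_SL": 0.00015861044253058927,
  "Ca_cleft": 0.00020262126433696038,
  "Ca_SR": 0.52157609540637,
  "TnC": 0.007321482238932732,
  "CaM_buf": 0.0003480012724590147,
  "SRB": 0.0014645660795398654,
  "SLL_SL": 0.004823512773541122,
  "SLH_SL": 0.10464141518978062,
  "SLL_cleft": 0.023035163513872057,
  "SLH_cleft": 0.4074298692834475,
  "CSQN": 2.6711502490770234,
  "CaMKII_act": 0.07283198384265524,
  "Ph_PLB": 0.014480593352256092
 }
}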