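{
 "format": "mouseatria-state-v1",
 "digest": "ec1aa04a3ce9",
 "state": {
  "V": -85.84579800976513,
  "m_Na": 0.001342128051454844,
  "h_Na": 0.9874973806950746,
  "j_Na": 0.9920347505535292,
  "mL": 0.00028353567670118723,
  "hL": 0.4399509419478982,
  "x_ss": 0.005936041905912875,
  "ICaL_C2": 0.9999619295526379,
  "ICaL_C1": 2.544051248159428e-07,
  "ICaL_O": 2.4304386516141407e-07,
  "ICaL_IV1": 2.091412267636096e-05,
  "ICaL_IV2": 1.4409130717662626e-05,
  "ICaL_ICa": 2.1267054187204975e-06,
  "ICaL_ICaV": 1.2303978935379827e-07,
  "Ito_C3": 0.937525369055453,
  "Ito_C2": 0.06089819262272572,
  "Ito_C1": 0.0013185741679051695,
  "Ito_O": 9.516641673016342e-06,
  "Ito_If": 3.16747066916243e-06,
  "Ito_Is": 7.084678953648326e-07,
  "Ito_CI": 0.0002444715727419934,
  "IKur_C1": 0.9480846184680315,
  "IKur_C2": 0.05088215326582891,
  "IKur_C3": 0.0010240357791109387,
  "IKur_C4": 9.159721751993564e-06,
  "IKur_O": 3.0724514854466736e-08,
  "IKur_I": 2.0411140260193428e-09,
  "IKr_C1": 0.9161385147520685,
  "IKr_C2": 0.01801618913387946,
  "IKr_C3": 0.0655157864505839,
  "IKr_O": 0.0002813064519933566,
  "IKr_I": 4.8203211541259755e-05,
  "RyR_R": 0.8523159145215115,
  "RyR_O": 1.3045053537765175e-06,
  "RyR_I": 2.2603389885943862e-07,
  "RyR_RI": 0.14768255493896115,
  "Na_i": 10.697776716646535,
  "K_i": 139.36932697258575,
  "Cl_i": 7.265122909717715,
  "Ca_i": 0.00010295476249553808,
  "Ca_SL": 0.00015813581550872715,
  "Ca_cleft": 0.00020157877015362374,
  "Ca_SR": 0.5213110968963641,
  "TnC": 0.00731813619353781,
  "CaM_buf": 0.00034781524326198945,
  "SRB": 0.0014638899502344483,
  "SLL_SL": 0.004809217959608149,
  "SLH_SL": 0.10442310406413355,
  "SLL_cleft": 0.022918219221596852,
  "SLH_cleft": 0.40612395980097277,
  "CSQN": 2.6703971318570026,
  "CaMKII_act": 0.07239995955248002,
  "Ph_PLB": 0.014454316183135411
 }
}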