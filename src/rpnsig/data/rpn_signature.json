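{
 "schema_version": 1,
 "mode": "weights_only",
 "hyperparams": {
  "k_best": 25,
  "l1_ratio": 0.999,
  "alpha": 0.005
 },
 "provenance": {
  "training_label": "study1",
  "note": "published resting-state pain-sensitivity network (RPN) signature: 21 non-zero partial-correlation connection weights; scaler parameters and intercept were not published, so scores are defined up to an affine map"
 },
 "entries": [
  {
   "i_label": "PO/pSTG",
   "i_module": "VAN + SN + BG + Thal",
   "atlas_idx_i": 119,
   "j_label": "pPut",
   "j_module": "VAN + SN + BG + Thal",
   "atlas_idx_j": 25,
   "weight": 0.27
  },
  {
   "i_label": "FP",
   "i_module": "FPN",
   "atlas_idx_i": 75,
   "j_label": "5CER",
   "j_module": "CER",
   "atlas_idx_j": 48,
   "weight": 0.245
  },
  {
   "i_label": "pCVI",
   "i_module": "CER",
   "atlas_idx_i": 9,
   "j_label": "SMC",
   "j_module": "VAN + SN + BG + Thal",
   "atlas_idx_j": 28,
   "weight": -0.2
  },
  {
   "i_label": "R aCrus2",
   "i_module": "CER",
   "atlas_idx_i": 62,
   "j_label": "lPrCG",
   "j_module": "SMN",
   "atlas_idx_j": 93,
   "weight": 0.15
  },
  {
   "i_label": "dPrCG",
   "i_module": "SMN",
   "atlas_idx_i": 67,
   "j_label": "pmVN",
   "j_module": "VN",
   "atlas_idx_j": 51,
   "weight": -0.102
  },
  {
   "i_label": "pdlVN",
   "i_module": "VN",
   "atlas_idx_i": 43,
   "j_label": "mVN",
   "j_module": "VN",
   "atlas_idx_j": 40,
   "weight": 0.095
  },
  {
   "i_label": "L IPL",
   "i_module": "DMN",
   "atlas_idx_i": 114,
   "j_label": "mean GM",
   "j_module": "mean GM",
   "atlas_idx_j": null,
   "weight": -0.086
  },
  {
   "i_label": "vCaud",
   "i_module": "VAN + SN + BG + Thal",
   "atlas_idx_i": 2,
   "j_label": "plVN",
   "j_module": "VN",
   "atlas_idx_j": 39,
   "weight": 0.085
  },
  {
   "i_label": "Acc",
   "i_module": "MLN",
   "atlas_idx_i": 78,
   "j_label": "pvmVN",
   "j_module": "VN",
   "atlas_idx_j": 107,
   "weight": -0.073
  },
  {
   "i_label": "CF",
   "i_module": "MLN",
   "atlas_idx_i": 79,
   "j_label": "vlPrCG",
   "j_module": "SMN",
   "atlas_idx_j": 110,
   "weight": -0.062
  },
  {
   "i_label": "5CER",
   "i_module": "CER",
   "atlas_idx_i": 48,
   "j_label": "pdlVN",
   "j_module": "VN",
   "atlas_idx_j": 43,
   "weight": -0.059
  },
  {
   "i_label": "pThal/Hb",
   "i_module": "VAN + SN + BG + Thal",
   "atlas_idx_i": 36,
   "j_label": "plVN",
   "j_module": "VN",
   "atlas_idx_j": 39,
   "weight": 0.058
  },
  {
   "i_label": "dCVI",
   "i_module": "CER",
   "atlas_idx_i": 44,
   "j_label": "lOTG",
   "j_module": "FPN",
   "atlas_idx_j": 117,
   "weight": -0.057
  },
  {
   "i_label": "dCiX",
   "i_module": "CER",
   "atlas_idx_i": 11,
   "j_label": "L vMFG",
   "j_module": "FPN",
   "atlas_idx_j": 105,
   "weight": -0.056
  },
  {
   "i_label": "R IPS",
   "i_module": "FPN",
   "atlas_idx_i": 20,
   "j_label": "plVN",
   "j_module": "VN",
   "atlas_idx_j": 39,
   "weight": -0.054
  },
  {
   "i_label": "avIns",
   "i_module": "VAN + SN + BG + Thal",
   "atlas_idx_i": 12,
   "j_label": "admVN",
   "j_module": "VN",
   "atlas_idx_j": 19,
   "weight": -0.044
  },
  {
   "i_label": "R aMFG",
   "i_module": "FPN",
   "atlas_idx_i": 58,
   "j_label": "lPoCG",
   "j_module": "VAN + SN + BG + Thal",
   "atlas_idx_j": 102,
   "weight": 0.043
  },
  {
   "i_label": "CrusI",
   "i_module": "CER",
   "atlas_idx_i": 84,
   "j_label": "dPoCG",
   "j_module": "VAN + SN + BG + Thal",
   "atlas_idx_j": 116,
   "weight": -0.017
  },
  {
   "i_label": "pgACC",
   "i_module": "DMN",
   "atlas_idx_i": 115,
   "j_label": "mSTG",
   "j_module": "VAN + SN + BG + Thal",
   "atlas_idx_j": 88,
   "weight": 0.009
  },
  {
   "i_label": "Precun",
   "i_module": "DMN",
   "atlas_idx_i": 103,
   "j_label": "LOG",
   "j_module": "MLN",
   "atlas_idx_j": 109,
   "weight": -0.003
  },
  {
   "i_label": "vThal",
   "i_module": "VAN + SN + BG + Thal",
   "atlas_idx_i": 36,
   "j_label": "FEF",
   "j_module": "VAN + SN + BG + Thal",
   "atlas_idx_j": 113,
   "weight": -0.001
  }
 ]
}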