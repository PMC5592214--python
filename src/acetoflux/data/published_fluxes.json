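{
  "description": "Published 33-flux vectors for the PQQ-ADH over-expressing (engineered) strain of A. pasteurianus JST-S and its parent (original) strain, as reported for the 48 h fermentation point, rounded to 4 decimals. Units mmol gDW^-1 h^-1. The measured exchange rates embedded in each vector (glucose uptake p1, ethanol uptake p15, total acetate formation p14+p16, biomass p33) are the inputs of the case study; the remaining entries are the published solved fluxes used here for cross-validation.",
  "exchange_rates": {
    "engineered": {"glc_uptake": 0.2337, "etoh_uptake": 7.8889, "acetate_formation": 8.2110, "biomass_rate": 0.8401},
    "original": {"glc_uptake": 0.2574, "etoh_uptake": 5.1262, "acetate_formation": 5.2586, "biomass_rate": 0.8401}
  },
  "fluxes": {
    "engineered": {
      "p1": 0.2337, "p2": 0.1146, "p3": 0.1146, "p4": 0.0357, "p5": 0.0714,
      "p6": 0.1489, "p7": 0.4384, "p8": 0.3708, "p9": 0.0618, "p10": 0.0849,
      "p11": 0.3221, "p12": 0.0145, "p13": 0.0578, "p14": 0.3221, "p15": 7.8889,
      "p16": 7.8889, "p17": 0.0814, "p18": 0.0814, "p19": 0.0814, "p20": 0.0791,
      "p21": 0.0791, "p22": 0.0791, "p23": 0.0791, "p24": 0.0045, "p25": 0.0075,
      "p26": 0.0014, "p27": 0.0011, "p28": 0.0058, "p29": 0.0072, "p30": 0.0035,
      "p31": 0.0016, "p32": 0.0023, "p33": 0.8401
    },
    "original": {
      "p1": 0.2574, "p2": 0.1265, "p3": 0.1265, "p4": 0.0397, "p5": 0.0793,
      "p6": 0.1647, "p7": 0.4859, "p8": 0.4115, "p9": 0.0686, "p10": 0.3204,
      "p11": 0.1324, "p12": 0.0162, "p13": 0.0646, "p14": 0.1324, "p15": 5.1262,
      "p16": 5.1262, "p17": 0.3169, "p18": 0.3169, "p19": 0.3169, "p20": 0.3146,
      "p21": 0.3146, "p22": 0.3146, "p23": 0.3146, "p24": 0.0045, "p25": 0.0075,
      "p26": 0.0014, "p27": 0.0011, "p28": 0.0058, "p29": 0.0072, "p30": 0.0035,
      "p31": 0.0016, "p32": 0.0023, "p33": 0.8401
    }
  }
}
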