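{
  "name": "jst_s",
  "description": "Central carbon metabolic network of Acetobacter pasteurianus JST-S growing on glucose plus ethanol: glycolysis (EMP), pentose phosphate pathway, the periplasmic ethanol oxidation chain (PQQ-ADH, ALDH), pyruvate metabolism and the TCA cycle, with nine biomass precursor drains and four measured exchange rates. Flux variables p1..p33 in mmol gDW^-1 h^-1. Cofactor species in reaction strings are annotation only and are not balanced.",
  "n_fluxes": 33,
  "metabolites": [
    {"id": "G6P", "name": "glucose 6-phosphate", "balanced": true},
    {"id": "F6P", "name": "fructose 6-phosphate", "balanced": true},
    {"id": "Ru5P", "name": "ribulose 5-phosphate", "balanced": true},
    {"id": "G3P", "name": "glyceraldehyde 3-phosphate", "balanced": true},
    {"id": "PEP", "name": "phosphoenolpyruvate", "balanced": true},
    {"id": "Pyr", "name": "pyruvate", "balanced": true},
    {"id": "AcCoA", "name": "acetyl coenzyme A", "balanced": true},
    {"id": "ACH", "name": "acetaldehyde", "balanced": true},
    {"id": "Cit", "name": "citrate", "balanced": true},
    {"id": "Isoc", "name": "isocitrate", "balanced": true},
    {"id": "aKet", "name": "alpha-ketoglutarate", "balanced": true},
    {"id": "Suc", "name": "succinate", "balanced": true},
    {"id": "Fum", "name": "fumarate", "balanced": true},
    {"id": "Mal", "name": "malate", "balanced": true},
    {"id": "OAA", "name": "oxaloacetate", "balanced": true},
    {"id": "Glc", "name": "glucose (extracellular)", "balanced": false},
    {"id": "EtOH", "name": "ethanol (extracellular)", "balanced": false},
    {"id": "Ace", "name": "acetate (extracellular)", "balanced": false},
    {"id": "Lac", "name": "lactate (not balanced)", "balanced": false},
    {"id": "BM", "name": "biomass", "balanced": false}
  ],
  "balance_equations": [
    {"row": 1, "label": "G6P", "kind": "balance", "terms": {"p1": "1", "p2": "-1", "p3": "-1", "p24": "-1"}},
    {"row": 2, "label": "G6P branch ratio", "kind": "ratio", "terms": {"p2": "1", "p3": "-1"}},
    {"row": 3, "label": "F6P", "kind": "balance", "terms": {"p2": "1", "p4": "1", "p6": "-1", "p26": "-1"}},
    {"row": 4, "label": "Ru5P", "kind": "balance", "terms": {"p3": "1", "p4": "-1", "p5": "-1", "p25": "-1"}},
    {"row": 5, "label": "Ru5P branch ratio", "kind": "ratio", "terms": {"p4": "1", "p5": "-0.5"}},
    {"row": 6, "label": "G3P", "kind": "balance", "terms": {"p5": "1", "p6": "1", "p7": "-0.5", "p27": "-1"}},
    {"row": 7, "label": "PEP", "kind": "balance", "terms": {"p7": "1", "p8": "-1", "p9": "-1", "p28": "-1"}},
    {"row": 8, "label": "PEP branch ratio", "kind": "ratio", "terms": {"p8": "1", "p9": "-6"}},
    {"row": 9, "label": "Pyr", "kind": "balance", "terms": {"p8": "1", "p10": "-1", "p11": "-1", "p12": "-1", "p13": "1", "p29": "-1"}},
    {"row": 10, "label": "Pyr branch ratio", "kind": "ratio", "terms": {"p12": "4", "p13": "-1"}},
    {"row": 11, "label": "Pyr->Ace route", "kind": "ratio", "terms": {"p11": "1", "p14": "-1"}},
    {"row": 12, "label": "AcCoA", "kind": "balance", "terms": {"p10": "1", "p17": "-1", "p30": "-1"}},
    {"row": 13, "label": "ACH", "kind": "balance", "terms": {"p15": "1", "p16": "-1"}},
    {"row": 14, "label": "Cit", "kind": "balance", "terms": {"p17": "1", "p18": "-1"}},
    {"row": 15, "label": "Isoc", "kind": "balance", "terms": {"p18": "1", "p19": "-1"}},
    {"row": 16, "label": "aKet", "kind": "balance", "terms": {"p19": "1", "p20": "-1", "p32": "-1"}},
    {"row": 17, "label": "Suc", "kind": "balance", "terms": {"p20": "1", "p21": "-1"}},
    {"row": 18, "label": "Fum", "kind": "balance", "terms": {"p21": "1", "p22": "-1"}},
    {"row": 19, "label": "Mal", "kind": "balance", "terms": {"p22": "1", "p23": "-1"}},
    {"row": 20, "label": "OAA", "kind": "balance", "terms": {"p9": "1", "p13": "-1", "p17": "-1", "p23": "1", "p31": "-1"}}
  ],
  "drains": [
    {"row": 21, "flux": "p24", "pool": "G6P"},
    {"row": 22, "flux": "p25", "pool": "Ru5P"},
    {"row": 23, "flux": "p26", "pool": "F6P"},
    {"row": 24, "flux": "p27", "pool": "G3P"},
    {"row": 25, "flux": "p28", "pool": "PEP"},
    {"row": 26, "flux": "p29", "pool": "Pyr"},
    {"row": 27, "flux": "p30", "pool": "AcCoA"},
    {"row": 28, "flux": "p31", "pool": "OAA"},
    {"row": 29, "flux": "p32", "pool": "aKet"}
  ],
  "coefficient_sets": {
    "as_printed": {
      "G6P": "0.005349",
      "F6P": "0.001644",
      "Ru5P": "0.008948",
      "G3P": "0.001291",
      "PEP": "0.006889",
      "Pyr": "0.03604",
      "AcCoA": "0.004139",
      "OAA": "0.01959",
      "aKet": "0.002744"
    },
    "reconciled": {
      "G6P": "0.005349",
      "F6P": "0.001644",
      "Ru5P": "0.008948",
      "G3P": "0.001291",
      "PEP": "0.006889",
      "Pyr": "0.008571",
      "AcCoA": "0.004139",
      "OAA": "0.001904",
      "aKet": "0.002744"
    }
  },
  "exchanges": [
    {"row": 30, "rate": "glc_uptake", "terms": {"p1": "1"}},
    {"row": 31, "rate": "etoh_uptake", "terms": {"p15": "1"}},
    {"row": 32, "rate": "acetate_formation", "terms": {"p14": "1", "p16": "1"}},
    {"row": 33, "rate": "biomass_rate", "terms": {"p33": "1"}}
  ],
  "reactions": [
    {"number": 1, "enzyme": "Glucokinase", "equation": "ATP + Glc = ADP + G6P", "fluxes": ["p1"]},
    {"number": 2, "enzyme": "Glucose-phosphate-isomerase", "equation": "G6P = F6P", "fluxes": ["p2"]},
    {"number": 3, "enzyme": "Glucose-6-phosphate dehydrogenase", "equation": "G6P + 2 NADP+ = 2 NADPH + Ru5P + CO2", "fluxes": ["p3"]},
    {"number": 4, "enzyme": "Transketolase/Transaldolase", "equation": "3 Ru5P = 2 F6P + G3P", "fluxes": ["p4", "p5"]},
    {"number": 5, "enzyme": "Phosphofructokinase/Aldolase/Triose-phosphate-isomerase", "equation": "ATP + F6P = ADP + 2 G3P", "fluxes": ["p6"]},
    {"number": 6, "enzyme": "Enolase/Phosphoglycerate-kinase/Phosphoglyceromutase/Glyceraldehyde-phosphate-dehydrogenase", "equation": "G3P + NAD+ + Pi + ADP = PEP + NADH + ATP + H2O + H+", "fluxes": ["p7"]},
    {"number": 7, "enzyme": "Pyruvate-kinase", "equation": "ADP + PEP = ATP + Pyr", "fluxes": ["p8"]},
    {"number": 8, "enzyme": "Phosphoenolpyruvate-carboxykinase", "equation": "CO2 + PEP + ADP = OAA + ATP", "fluxes": ["p9"]},
    {"number": 9, "enzyme": "Pyruvate dehydrogenase", "equation": "Pyr + CoA + NAD+ = Ac-CoA + CO2 + NADH", "fluxes": ["p10"]},
    {"number": 10, "enzyme": "Pyruvate decarboxylase", "equation": "Pyr = ACH + CO2", "fluxes": ["p11"]},
    {"number": 11, "enzyme": "Lactate dehydrogenase", "equation": "Pyr + NADH + H+ = Lac + NAD+", "fluxes": []},
    {"number": 12, "enzyme": "Pyruvate carboxylase", "equation": "ATP + Pyr + HCO3- = ADP + Pi + OAA", "fluxes": ["p12"]},
    {"number": 13, "enzyme": "Phosphotransacetylase/acetate kinase", "equation": "Ac-CoA + Pi + ADP = CoA + Ace + ATP", "fluxes": []},
    {"number": 14, "enzyme": "Alcohol dehydrogenase (PQQ-ADH)", "equation": "EtOH + NAD+ = ACH + NADH + H+", "fluxes": ["p15"]},
    {"number": 15, "enzyme": "Acetaldehyde dehydrogenase (ALDH)", "equation": "ACH + NAD+ = Ace + NADH + H+", "fluxes": ["p16"]},
    {"number": 16, "enzyme": "Citrate synthase", "equation": "Ac-CoA + H2O + OAA = Cit + CoA", "fluxes": ["p17"]},
    {"number": 17, "enzyme": "Aconitase", "equation": "Cit = Isoc", "fluxes": ["p18"]},
    {"number": 18, "enzyme": "Isocitrate dehydrogenase", "equation": "Isoc + NADP+ = aKet + NADPH + CO2", "fluxes": ["p19"]},
    {"number": 19, "enzyme": "Oxoglutarate dehydrogenase complex", "equation": "aKet + NAD+ = Suc + NADH + H+ + CO2", "fluxes": ["p20"]},
    {"number": 20, "enzyme": "Fumarate reductase", "equation": "Suc + FAD+ = Fum + FADH", "fluxes": ["p21"]},
    {"number": 21, "enzyme": "Fumarate hydratase", "equation": "Fum + H2O = Mal", "fluxes": ["p22"]},
    {"number": 22, "enzyme": "Malate dehydrogenase", "equation": "Mal + NAD+ = OAA + NADH + H+", "fluxes": ["p23"]}
  ]
}
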