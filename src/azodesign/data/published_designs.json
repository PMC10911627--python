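{
  "comment": "Growth-coupled strain designs for ACT production from methyl red, as printed for the genome-scale model (iJN1462c). thresholds = [min biomass %, min ACT %]. table3 columns: substrate_uptake, growth, act_flux, min_guaranteed_yield, yield_at_optimum_growth (mmol gDW^-1 h^-1 based).",
  "baseline": {
    "model": "iJN1462c",
    "table3": {"substrate_uptake": 9.176, "growth": 0.5976, "act_flux": 0.0,
               "min_guaranteed_yield": 0.0, "yield_at_optimum_growth": 0.0}
  },
  "designs": [
    {
      "id": 1,
      "thresholds": [0, 0],
      "reaction_knockouts": ["MALS", "FDH", "SUCD4", "ALDD2y", "ALDD2x",
                             "SUCDi", "GLYOX", "NACODA", "PGL"],
      "gene_knockouts": ["PP_0356", "PP_2183", "PP_0489", "PP_4203", "PP_2589",
                         "PP_0545", "PP_2694", "PP_4190", "PP_2492", "PP_4144",
                         "PP_5186", "PP_1023"],
      "table3": {"substrate_uptake": 7.431, "growth": 0.01270, "act_flux": 0.4599,
                 "min_guaranteed_yield": 0.01145, "yield_at_optimum_growth": 0.06190}
    },
    {
      "id": 2,
      "thresholds": [1, 0],
      "reaction_knockouts": ["MALS", "ALDD2y", "MTHFC", "ALDD2x", "SUCDi",
                             "GLYOX", "NACODA", "ACACt2pp", "RPE"],
      "gene_knockouts": ["PP_0356", "PP_2492", "PP_2265", "PP_1945", "PP_2589",
                         "PP_0545", "PP_2694", "PP_4190", "PP_4144", "PP_5186",
                         "PP_0415", "PP_3124"],
      "table3": {"substrate_uptake": 7.428, "growth": 0.01235, "act_flux": 0.4599,
                 "min_guaranteed_yield": 0.01145, "yield_at_optimum_growth": 0.06192}
    },
    {
      "id": 4,
      "thresholds": [1, 1],
      "reaction_knockouts": ["SUCOAS", "HIBDkt", "PUTA3", "ALDD2y", "GLYOX",
                             "ACS2", "PPS", "ACONTb", "GLYO1", "PGL",
                             "ACACt2pp", "MDH", "ALDD2x", "NTD11", "FTHFD",
                             "PC", "GARFT", "ICL", "IMPD", "P5CD"],
      "gene_knockouts": ["PP_4186", "PP_4666", "PP_4947", "PP_2492", "PP_4144",
                         "PP_2351", "PP_2339", "PP_2112", "PP_2082", "PP_1023",
                         "PP_0612", "PP_3124", "PP_0654", "PP_2589", "PP_0545",
                         "PP_2694", "PP_1620", "PP_0327", "PP_1367", "PP_1943",
                         "PP_1664", "PP_5347", "PP_4116", "PP_1031"],
      "table3": {"substrate_uptake": 7.018, "growth": 0.01231, "act_flux": 0.3214,
                 "min_guaranteed_yield": 0.002726, "yield_at_optimum_growth": 0.04579}
    },
    {
      "id": 5,
      "thresholds": [1, 5],
      "reaction_knockouts": ["ALDD2y", "FTHFD", "ALDD2x", "MDH", "MICITDr",
                             "GLYOX", "ACACT11", "MALS", "PGL", "ACONTa",
                             "NACODA"],
      "gene_knockouts": ["PP_2492", "PP_0327", "PP_1367", "PP_1943", "PP_2589",
                         "PP_0545", "PP_2694", "PP_0654", "PP_2336", "PP_4144",
                         "PP_0356", "PP_1023", "PP_2112", "PP_2339", "PP_5186",
                         "PP_2137", "PP_2215"],
      "table3": {"substrate_uptake": 7.429, "growth": 0.01162, "act_flux": 0.4611,
                 "min_guaranteed_yield": 0.01145, "yield_at_optimum_growth": 0.06208}
    }
  ]
}
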