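{
  "newborn": {
    "n_screened": 111986,
    "n_primary_positive": 2464,
    "n_recalled": 2275,
    "n_confirmed": 30,
    "spectrum": [
      {"category": "AAMD", "disorder": null, "cases": 8, "printed_incidence": "1/13,998"},
      {"category": "AAMD", "disorder": "PKU", "cases": 6, "printed_incidence": "1/18,664"},
      {"category": "AAMD", "disorder": "CTLN2", "cases": 1, "printed_incidence": "1/111,986"},
      {"category": "AAMD", "disorder": "HCY", "cases": 1, "printed_incidence": "1/111,986"},
      {"category": "FAMD", "disorder": null, "cases": 15, "printed_incidence": "1/7,466"},
      {"category": "FAMD", "disorder": "PCD", "cases": 12, "printed_incidence": "1/9,332"},
      {"category": "FAMD", "disorder": "SCADD", "cases": 2, "printed_incidence": "1/55,993"},
      {"category": "FAMD", "disorder": "MCADD", "cases": 1, "printed_incidence": "1/111,986"},
      {"category": "OAMD", "disorder": null, "cases": 7, "printed_incidence": "1/15,998"},
      {"category": "OAMD", "disorder": "IVA", "cases": 3, "printed_incidence": "1/37,329"},
      {"category": "OAMD", "disorder": "MMA", "cases": 1, "printed_incidence": "1/111,986"},
      {"category": "OAMD", "disorder": "PA", "cases": 1, "printed_incidence": "1/111,986"},
      {"category": "OAMD", "disorder": "GA-1", "cases": 1, "printed_incidence": "1/111,986"},
      {"category": "OAMD", "disorder": "HMGCLD", "cases": 1, "printed_incidence": "1/111,986"},
      {"category": null, "disorder": null, "cases": 30, "printed_incidence": "1/3,733"}
    ]
  },
  "high_risk": {
    "n_screened": 7461,
    "n_confirmed": 19,
    "spectrum": [
      {"category": "AAMD", "disorder": null, "cases": 8, "printed_incidence": "1/933"},
      {"category": "AAMD", "disorder": "CTLN2", "cases": 4, "printed_incidence": "1/1,865"},
      {"category": "AAMD", "disorder": "OTC", "cases": 2, "printed_incidence": "1/3,731"},
      {"category": "AAMD", "disorder": "CPS1", "cases": 1, "printed_incidence": "1/7,461"},
      {"category": "AAMD", "disorder": "H-TYR", "cases": 1, "printed_incidence": "1/7,461"},
      {"category": "FAMD", "disorder": null, "cases": 6, "printed_incidence": "1/1,244"},
      {"category": "FAMD", "disorder": "PCD", "cases": 2, "printed_incidence": "1/3,731"},
      {"category": "FAMD", "disorder": "SCADD", "cases": 2, "printed_incidence": "1/3,731"},
      {"category": "FAMD", "disorder": "CPT2", "cases": 1, "printed_incidence": "1/7,461"},
      {"category": "FAMD", "disorder": "MADD", "cases": 1, "printed_incidence": "1/7,461"},
      {"category": "OAMD", "disorder": null, "cases": 5, "printed_incidence": "1/1,492"},
      {"category": "OAMD", "disorder": "GA-1", "cases": 2, "printed_incidence": "1/3,731"},
      {"category": "OAMD", "disorder": "MMA", "cases": 1, "printed_incidence": "1/7,461"},
      {"category": "OAMD", "disorder": "PA", "cases": 1, "printed_incidence": "1/7,461"},
      {"category": "OAMD", "disorder": "IVA", "cases": 1, "printed_incidence": "1/7,461"},
      {"category": null, "disorder": null, "cases": 19, "printed_incidence": "1/393"}
    ]
  },
  "carrier_study": {
    "gene": "SLC22A5",
    "n_screened": 2093,
    "n_carriers": 24,
    "variant_counts": {"c.51C>G": 13}
  }
}
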