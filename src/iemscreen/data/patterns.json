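{
  "version": "liuzhou-2012-2020",
  "note": "Per-disorder MS/MS signatures. reported_reference is the reference interval as printed alongside each disorder (kept as metadata; the screening cut-off table governs flagging). observed_primary / observed_recall are [median, min, max] in umol/L (ratios dimensionless) over the confirmed cases; single-case disorders have min = max = median. The one newborn citrullinemia case is labelled CTLN2 here as in the source tables, although the running text once calls it 'citrullinemia type l' - the labelling inconsistency is preserved, not resolved.",
  "patterns": [
    {
      "disorder": "PKU", "category": "AAMD", "cases": 6,
      "required": [["Phe", "high"], ["Phe/Tyr", "high"]],
      "reported_reference": {"Phe": [24.0, 116.0], "Phe/Tyr": [0.2, 2.0]},
      "observed_primary": {"Phe": [378.3, 201, 1000.5], "Phe/Tyr": [10.24, 3.02, 25.6]},
      "observed_recall": {"Phe": [376.9, 230.5, 789.3], "Phe/Tyr": [14.64, 4.77, 20.12]}
    },
    {
      "disorder": "CTLN2", "category": "AAMD", "cases": 5,
      "required": [["Cit", "high"], ["Met", "high"]],
      "reported_reference": {"Cit": [5, 41], "Met": [5, 38]},
      "observed_primary": {"Cit": [236.2, 128.3, 365.7], "Met": [129.0, 94.0, 181.5]},
      "observed_recall": {"Cit": [240.12, 134.8, 345.7], "Met": [145.5, 124.5, 163.2]}
    },
    {
      "disorder": "OTC", "category": "AAMD", "cases": 2,
      "required": [["Cit", "low"], ["Cit/Phe", "low"]],
      "reported_reference": {"Cit": [5, 41], "Cit/Phe": [0.14, 0.72]},
      "observed_primary": {"Cit": [1.85, 1.6, 2.1], "Cit/Phe": [0.095, 0.09, 0.1]},
      "observed_recall": {"Cit": [2.05, 1.8, 2.3], "Cit/Phe": [0.075, 0.06, 0.09]}
    },
    {
      "disorder": "CPS1", "category": "AAMD", "cases": 1,
      "required": [["Cit", "low"]],
      "reported_reference": {"Cit": [5, 41]},
      "observed_primary": {"Cit": [2.4, 2.4, 2.4]},
      "observed_recall": {"Cit": [2.8, 2.8, 2.8]}
    },
    {
      "disorder": "HCY", "category": "AAMD", "cases": 1,
      "required": [["Met", "high"], ["Met/Phe", "high"]],
      "reported_reference": {"Met": [5, 38], "Met/Phe": [0.25, 1.2]},
      "observed_primary": {"Met": [152.6, 152.6, 152.6], "Met/Phe": [2.65, 2.65, 2.65]},
      "observed_recall": {"Met": [480, 480, 480], "Met/Phe": [3.2, 3.2, 3.2]}
    },
    {
      "disorder": "H-TYR", "category": "AAMD", "cases": 1,
      "required": [["Tyr", "high"], ["Phe/Tyr", "low"]],
      "reported_reference": {"Tyr": [45, 260], "Phe/Tyr": [0.2, 2.0]},
      "observed_primary": {"Tyr": [526.0, 526.0, 526.0], "Phe/Tyr": [0.12, 0.12, 0.12]},
      "observed_recall": {"Tyr": [498.2, 498.2, 498.2], "Phe/Tyr": [0.14, 0.14, 0.14]}
    },
    {
      "disorder": "PCD", "category": "FAMD", "cases": 14,
      "required": [["C0", "low"]],
      "reported_reference": {"C0": [9.0, 55.0]},
      "observed_primary": {"C0": [2.83, 0.74, 5.45]},
      "observed_recall": {"C0": [3.95, 1.07, 5.82]}
    },
    {
      "disorder": "SCADD", "category": "FAMD", "cases": 4,
      "required": [["C4", "high"], ["C4/C2", "high"]],
      "reported_reference": {"C4": [0.06, 0.5], "C4/C2": [0, 0.03]},
      "observed_primary": {"C4": [1.99, 1.69, 2.49], "C4/C2": [0.09, 0.069, 0.114]},
      "observed_recall": {"C4": [2.06, 1.02, 2.84], "C4/C2": [0.11, 0.062, 0.169]}
    },
    {
      "disorder": "MCADD", "category": "FAMD", "cases": 1,
      "required": [["C8", "high"], ["C8/C2", "high"]],
      "reported_reference": {"C8": [0.01, 0.24], "C8/C2": [0, 0.1]},
      "observed_primary": {"C8": [1.89, 1.89, 1.89], "C8/C2": [0.19, 0.19, 0.19]},
      "observed_recall": {"C8": [3.53, 3.53, 3.53], "C8/C2": [0.42, 0.42, 0.42]}
    },
    {
      "disorder": "CPT2", "category": "FAMD", "cases": 1,
      "required": [["C16", "high"], ["C18", "high"], ["C18:1", "high"], ["(C16 + C18:1)/C2", "high"]],
      "reported_reference": {"C16": [0.3, 5.7], "C18": [0.14, 1.86], "C18:1": [0.3, 2.9], "(C16 + C18:1)/C2": [0.07, 0.4]},
      "observed_primary": {"C16": [24.2, 24.2, 24.2], "C18": [4.35, 4.35, 4.35], "C18:1": [4.65, 4.65, 4.65], "(C16 + C18:1)/C2": [14.0, 14.0, 14.0]},
      "observed_recall": {"C16": [28.6, 28.6, 28.6], "C18": [5.02, 5.02, 5.02], "C18:1": [4.36, 4.36, 4.36], "(C16 + C18:1)/C2": [13.8, 13.8, 13.8]}
    },
    {
      "disorder": "MADD", "category": "FAMD", "cases": 1,
      "required": [["C4", "high"], ["C5", "high"], ["C6", "high"], ["C8", "high"], ["C10", "high"], ["C12", "high"], ["C14", "high"]],
      "reported_reference": {"C4": [0.06, 0.5], "C5": [0.04, 0.5], "C6": [0.01, 0.1], "C8": [0.01, 0.24], "C10": [0.01, 0.3], "C12": [0.02, 0.3], "C14": [0.05, 0.4]},
      "observed_primary": {"C4": [2.59, 2.59, 2.59], "C5": [6.98, 6.98, 6.98], "C6": [0.62, 0.62, 0.62], "C8": [1.24, 1.24, 1.24], "C10": [1.7, 1.7, 1.7], "C12": [1.92, 1.92, 1.92], "C14": [2.44, 2.44, 2.44]},
      "observed_recall": {"C4": [2.64, 2.64, 2.64], "C5": [7.32, 7.32, 7.32], "C6": [0.56, 0.56, 0.56], "C8": [1.12, 1.12, 1.12], "C10": [1.58, 1.58, 1.58], "C12": [1.56, 1.56, 1.56], "C14": [2.68, 2.68, 2.68]}
    },
    {
      "disorder": "IVA", "category": "OAMD", "cases": 4,
      "required": [["C5", "high"], ["C5/C2", "high"]],
      "reported_reference": {"C5": [0.04, 0.5], "C5/C2": [0, 0.03]},
      "observed_primary": {"C5": [7.5, 5.6, 11.6], "C5/C2": [0.57, 0.35, 0.74]},
      "observed_recall": {"C5": [5.9, 4.32, 8.96], "C5/C2": [0.66, 0.48, 0.83]}
    },
    {
      "disorder": "GA-1", "category": "OAMD", "cases": 3,
      "required": [["C5DC", "high"], ["C5DC/C8", "high"]],
      "reported_reference": {"C5DC": [0.01, 0.2], "C5DC/C8": [0.2, 3.0]},
      "observed_primary": {"C5DC": [1.75, 0.98, 2.7], "C5DC/C8": [65.9, 17.5, 139.9]},
      "observed_recall": {"C5DC": [2.34, 1.58, 3.78], "C5DC/C8": [69.8, 26.5, 120.0]}
    },
    {
      "disorder": "MMA", "category": "OAMD", "cases": 2,
      "required": [["C3", "high"], ["C3/C2", "high"], ["C3/C0", "high"]],
      "reported_reference": {"C3": [0.35, 4.2], "C3/C2": [0.04, 0.25], "C3/C0": [0.03, 0.25]},
      "observed_primary": {"C3": [8.83, 8.7, 8.96], "C3/C2": [0.94, 0.56, 1.32], "C3/C0": [1.33, 0.46, 2.2]},
      "observed_recall": {"C3": [11.1, 8.32, 13.87], "C3/C2": [0.69, 0.62, 0.76], "C3/C0": [0.56, 0.51, 0.61]}
    },
    {
      "disorder": "PA", "category": "OAMD", "cases": 2,
      "required": [["C3", "high"], ["C3/C2", "high"], ["C3/C0", "high"]],
      "reported_reference": {"C3": [0.35, 4.2], "C3/C2": [0.04, 0.25], "C3/C0": [0.03, 0.25]},
      "observed_primary": {"C3": [9.67, 9.61, 9.73], "C3/C2": [2.24, 1.53, 2.94], "C3/C0": [1.57, 1.06, 2.08]},
      "observed_recall": {"C3": [8.3, 7.82, 8.78], "C3/C2": [1.16, 0.85, 1.46], "C3/C0": [1.58, 1.46, 1.69]}
    },
    {
      "disorder": "HMGCLD", "category": "OAMD", "cases": 1,
      "required": [["C5-OH", "high"], ["C5-OH/C3", "high"]],
      "reported_reference": {"C5-OH": [0.05, 0.6], "C5-OH/C3": [0.02, 0.4]},
      "observed_primary": {"C5-OH": [2.38, 2.38, 2.38], "C5-OH/C3": [4.65, 4.65, 4.65]},
      "observed_recall": {"C5-OH": [2.51, 2.51, 2.51], "C5-OH/C3": [1.02, 1.02, 1.02]}
    }
  ]
}
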