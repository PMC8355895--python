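{
  "version": "liuzhou-2012-2020",
  "boundary": "closed",
  "entries": [
    {"marker": "Ala", "lower": 120, "upper": 600, "source": "table1"},
    {"marker": "Gly", "lower": 170, "upper": 1150, "source": "table1"},
    {"marker": "Pro", "lower": 110, "upper": 400, "source": "table1"},
    {"marker": "Leu", "lower": 51, "upper": 295, "source": "table1"},
    {"marker": "Val", "lower": 45, "upper": 270, "source": "table1"},
    {"marker": "Met", "lower": 5, "upper": 38, "source": "table1"},
    {"marker": "Phe", "lower": 24, "upper": 116, "source": "table1"},
    {"marker": "Tyr", "lower": 45, "upper": 260, "source": "table1"},
    {"marker": "Cit", "lower": 5, "upper": 41, "source": "table1"},
    {"marker": "Orn", "lower": 42, "upper": 390, "source": "table1"},
    {"marker": "Arg", "lower": 1, "upper": 52, "source": "table1"},
    {"marker": "C0", "lower": 9.0, "upper": 55.0, "source": "table1"},
    {"marker": "C2", "lower": 8.0, "upper": 50.0, "source": "table1"},
    {"marker": "C3", "lower": 0.35, "upper": 4.2, "source": "table1"},
    {"marker": "C3DC", "lower": 0.02, "upper": 0.2, "source": "table1"},
    {"marker": "C4", "lower": 0.06, "upper": 0.5, "source": "table1"},
    {"marker": "C4-OH", "lower": 0.03, "upper": 0.4, "source": "table1"},
    {"marker": "C4DC", "lower": 0.05, "upper": 0.5, "source": "table1"},
    {"marker": "C5", "lower": 0.04, "upper": 0.5, "source": "table1"},
    {"marker": "C5:1", "lower": 0.0, "upper": 0.1, "source": "table1"},
    {"marker": "C5-OH", "lower": 0.05, "upper": 0.6, "source": "table1"},
    {"marker": "C5DC", "lower": 0.01, "upper": 0.2, "source": "table1"},
    {"marker": "C6", "lower": 0.02, "upper": 0.2, "source": "table1"},
    {"marker": "C6:1", "lower": 0.01, "upper": 0.1, "source": "table1"},
    {"marker": "C6DC", "lower": 0.0, "upper": 0.1, "source": "table1"},
    {"marker": "C8", "lower": 0.01, "upper": 0.24, "source": "table1"},
    {"marker": "C8:1", "lower": 0.04, "upper": 0.45, "source": "table1"},
    {"marker": "C8DC", "lower": 0.01, "upper": 0.1, "source": "table1"},
    {"marker": "C10", "lower": 0.02, "upper": 0.25, "source": "table1"},
    {"marker": "C10:1", "lower": 0.02, "upper": 0.25, "source": "table1"},
    {"marker": "C12", "lower": 0.03, "upper": 0.6, "source": "table1"},
    {"marker": "C12:1", "lower": 0.01, "upper": 0.3, "source": "table1"},
    {"marker": "C14", "lower": 0.07, "upper": 0.5, "source": "table1"},
    {"marker": "C14:1", "lower": 0.02, "upper": 0.4, "source": "table1"},
    {"marker": "C14-OH", "lower": 0.0, "upper": 0.1, "source": "table1"},
    {"marker": "C16", "lower": 0.3, "upper": 5.7, "source": "table1"},
    {"marker": "C16:1", "lower": 0.03, "upper": 0.45, "source": "table1"},
    {"marker": "C16-OH", "lower": 0.0, "upper": 0.1, "source": "table1"},
    {"marker": "C18", "lower": 0.14, "upper": 1.86, "source": "table1"},
    {"marker": "C18:1", "lower": 0.4, "upper": 3.0, "source": "table1"},
    {"marker": "C18-OH", "lower": 0.0, "upper": 0.05, "source": "table1"},
    {"marker": "C3/C0", "lower": 0.03, "upper": 0.25, "source": "table1"},
    {"marker": "C3/C2", "lower": 0.04, "upper": 0.25, "source": "table1"},
    {"marker": "C4/C2", "lower": 0.0, "upper": 0.03, "source": "table1"},
    {"marker": "C5/C2", "lower": 0.0, "upper": 0.03, "source": "table1"},
    {"marker": "C5-OH/C3", "lower": 0.02, "upper": 0.4, "source": "table1"},
    {"marker": "C5DC/C8", "lower": 0.2, "upper": 3.0, "source": "table1"},
    {"marker": "C8/C2", "lower": 0.0, "upper": 0.1, "source": "table1"},
    {"marker": "C14:1/C8:1", "lower": 0.1, "upper": 4.0, "source": "table1"},
    {"marker": "C0/(C16 + C18)", "lower": 2.0, "upper": 30.0, "source": "table1"},
    {"marker": "(C16 + C18:1)/C2", "lower": 0.07, "upper": 0.4, "source": "table1"},
    {"marker": "Phe/Tyr", "lower": 0.2, "upper": 2.0, "source": "table3-extension"},
    {"marker": "Cit/Phe", "lower": 0.14, "upper": 0.72, "source": "table3-extension"},
    {"marker": "Met/Phe", "lower": 0.25, "upper": 1.2, "source": "table3-extension"}
  ]
}
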