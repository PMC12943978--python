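{
  "compound_id": "B-134-0",
  "counts": {"F": 2, "I": 6, "J": 2, "P": 2, "Delta": 2, "Th": 2, "Phi17": 2},
  "h_correction": 8,
  "formula_h": 26,
  "smiles": "COc1cc(Br)cc(C=NCCOCCOCCN=Cc2cc(Br)cc(OC)c2O)c1O"
}
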