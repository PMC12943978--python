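{
  "label": "B-134-0",
  "e_homo_ev": -6.899,
  "e_lumo_ev": -1.627
}
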