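# Worked example: six paclitaxel reports, hand-checkable 2x2 table (1,1,1,3).
arms:
  pharmacovigilance:
    inputs:
      drugs: examples/toy_drug.txt
      reacs: examples/toy_reac.txt
    target_drug: paclitaxel
    groups:
      tamsulosin: [tamsulosin]
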