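# Demo run: all three arms on synthetic data (seed 17).
seed: 17
arms:
  pharmacovigilance:
    generate:
      n_reports: 20000
      exposure_odds_multiplier: 0.5
    target_drug: paclitaxel
  vonfrey:
    generate:
      n_sessions_per_group: 8
      slope: 8.0
      groups:
        vehicle: 12.0
        paclitaxel: 2.0
  morphometry:
    generate:
      groups:
        control: {n_fibers: 60, degeneration_level: 0.0}
        degenerated: {n_fibers: 60, degeneration_level: 0.6}
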