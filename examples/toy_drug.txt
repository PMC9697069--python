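report_id$drug_name
r1$paclitaxel
r1$tamsulosin
r2$paclitaxel
r2$tamsulosin
r3$paclitaxel
r4$paclitaxel
r5$paclitaxel
r6$paclitaxel
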