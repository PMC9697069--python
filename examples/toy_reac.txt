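report_id$event_term
r1$peripheral neuropathy
r3$peripheral sensory neuropathy
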