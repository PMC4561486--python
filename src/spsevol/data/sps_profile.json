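{
 "sec_column": 60,
 "description": "synthetic SPS seed profile (hand-built fixture, not real sequences)"
}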