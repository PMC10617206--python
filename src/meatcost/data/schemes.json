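{
  "red_meat": {"boundaries": [70, 140, 210, 280], "zero_band": false},
  "processed_meat": {"boundaries": [50, 100, 150], "zero_band": true}
}
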