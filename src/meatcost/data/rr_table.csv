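exposure,sex,rr,ci_lower,ci_upper,increment_g_per_day
red_meat,male,1.12,1.00,1.25,100
red_meat,female,1.12,1.00,1.25,100
processed_meat,male,1.16,1.08,1.26,50
processed_meat,female,1.16,1.08,1.26,50
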