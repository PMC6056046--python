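# FSE T2-weighted pre-contrast optimization with the in-vivo echo spacing
# pinned (7.4 ms); ETL, TR and NSA follow under the 5-minute budget.

[tissues]
condition = "pre"

[snr]
exponent_p = 1.0

[plan]
preset = "fset2_pre"

[plan.overrides]
esp_ms = 7.4
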