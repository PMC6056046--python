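# FSE T1-weighted pre-contrast optimization.  The echo spacing is pinned to
# the in-vivo value 7.4 ms (the simulated ESP winner trades image quality for
# bandwidth and fails the comparison analysis), then ETL, TR and NSA are
# optimized under the 5-minute budget.

[tissues]
condition = "pre"

[snr]
exponent_p = 1.0

[plan]
preset = "fset1_pre"

[plan.overrides]
esp_ms = 7.4
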