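# FLAIR pre-contrast optimization: TI sweep (CSF nulling), then the long-TR
# sweep with its coupled minimum-ETL schedule under the 10-minute limit.

[tissues]
condition = "pre"

[snr]
exponent_p = 1.0

[plan]
preset = "flair_pre"
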