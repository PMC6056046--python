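# Single-sequence evaluation at the optimal in-vivo FSE T2-weighted protocol.

[tissues]
condition = "pre"

[snr]
exponent_p = 1.0

[sequence]
type = "fse"
tr_ms = 7000.0
esp_ms = 7.4
etl = 15
nsa = 3
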