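# Spoiled GRE post-contrast optimization: flip-angle sweep at minimum TR,
# then TR with maximal NSA under the 5-minute budget.

[tissues]
condition = "post"

[snr]
exponent_p = 1.0

[plan]
preset = "gre_post"
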