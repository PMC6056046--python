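# 3D MP-RAGE post-contrast optimization: TI sweep (minTR timing), then
# flip angle with maximal NSA under the 5-minute budget.

[tissues]
condition = "post"

[geometry]
fov_x_mm = 20.0
fov_y_mm = 20.0
dz_mm = 0.15625
n_fe = 128
n_pe = 128
n_slices_or_nz = 128
mode = "3D"
bw = 75.0

[snr]
exponent_p = 1.0

[plan]
preset = "mprage_post"
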