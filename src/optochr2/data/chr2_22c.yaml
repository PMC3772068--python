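e12_dark: 0.011
e21_dark: 0.008
e_rev: 0.0
eps1: 0.8535
eps2: 0.14
flux_coeff: 0.0006
g_chr2: 0.4
gamma: 0.1
gd1_amp: 0.043
gd1_base: 0.075
gd1_v0: 20.0
gd1_vs: -20.0
gd2: 0.05
gr_pref: 4.34587e-05
gr_slope: 0.0211539274
hc: 1.986446e-25
k1_scale: 1.0
k2_scale: 1.0
lambda_max: 470.0
log_c1_12: 0.005
log_c1_21: 0.004
log_c2: 0.024
q10_e12: 1.5
q10_e21: 2.5
q10_gd1: 2.3
q10_gd2: 2.3
q10_gr: 2.3
q10_k1: 1.0
q10_k2: 1.0
rect_a: 10.6408
rect_b: 14.6408
rect_vs: 42.7671
sigma_ret: 1.2e-19
tau_chr2: 1.3
temp: 22.0
temp_ref: 22.0
theta_scale: 100.0
w_loss: 0.77
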