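N: 100
b: 0.1
r0: 0.0
e0: 75.0
w0: 0.8
eta: 0.2
c_r_pos: 1.0
c_r_neg: 1.0
v_n: 1.0
v_r_pos: 0.5
v_r_neg: 0.5
v_o_pos: 0.1
v_o_neg: -100.0
d: 10
mu_r: 0.0
mu_e: 0.0
mu_w: 0.01
sigma_r: 0.01
sigma_e: 1.0
sigma_w: 0.01
lit_capacity: 1000000
n_steps: 1000000
sample_interval: 2000
seed: 1
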