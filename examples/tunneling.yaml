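# Stochastic tunneling of a highly fit mutant clone:
# expected result ~96.5% mutant-first fixation.
N: 1000
M: 20000
n_total: 1000
n_cancer: 100        # 10% of N; reconstructed initial condition
f_h: 1.0
f_c: 1.1
f_m: 3.0
r_m: 0.01
seed: 1
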