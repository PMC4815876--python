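phases:
  - name: cementite
    cell: [4.51, 5.05, 6.73, 90, 90, 90]
    grains: 5
sigma: 0.0001
q_max: 0.6
d_star_min: 0.1
N_u1: 2000
N_u2: 1000
N_j: 5
N_t: 10
seed: 7
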