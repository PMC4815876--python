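# Four-mineral granite mixture, reference parameterization (scaled direction counts)
phases:
  - name: quartz
    cell: [4.92, 4.92, 5.40, 90, 90, 120]
    grains: 5
  - name: biotite
    cell: [5.33, 9.23, 10.17, 90, 100.16, 90]
    grains: 5
  - name: orthoclase
    cell: [8.56, 13.00, 7.19, 90, 116.02, 90]
    grains: 5
  - name: plagioclase
    cell: [8.19, 12.88, 14.12, 93.30, 115.79, 91.12]
    grains: 5
sigma: 0.0001
q_max: 0.5
d_star_min: 0.05
N_u1: 3000
N_u2: 1500
N_j: 5
N_t: 20
seed: 1
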