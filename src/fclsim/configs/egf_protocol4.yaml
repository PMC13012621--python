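# EGF stimulus protocol 4: at t=0 AP-2 100 -> 200, gated clathrin-clathrin
# rate x50 and clathrin diffusion x1/50 simultaneously; all reverted at
# 30 min. Start from a preassembled single cluster.
box_edge: "1 um"
dt: "3 us"
n_clathrin: 300
n_ap2: 100
duration: "60 min"
frame_interval: "0.1 s"
rates:
  k_cc_gated: "50x0.913 uM-1s-1"
  k_ap2_clat: "0.0012 uM-1s-1"
  koff_cc: "1 s-1"
  koff_ap2_clat: "1e-4 s-1"
diffusion:
  d_clat: "13 um2/s"
schedule:
  - time: "0 us"
    n_ap2: 200
    k_cc_gated_mult: 50
    d_clat_mult: 0.02
  - time: "30 min"
initial_condition:
  type: preassembled
  cluster_size: 60
seed: 0
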