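# Reference membrane-patch conditions: 1 um box, 300 clathrins, 150 AP-2,
# 30 simulated minutes. Cluster-compute scale (~6e8 steps).
box_edge: "1 um"
dt: "3 us"
n_clathrin: 300
n_ap2: 150
duration: "30 min"
frame_interval: "0.1 s"
rates:
  k_cc_gated: "50x0.913 uM-1s-1"
  k_cc_free: "0 uM-1s-1"
  k_ap2_clat: "0.0012 uM-1s-1"
  koff_cc: "1 s-1"
  koff_ap2_clat: "1e-4 s-1"
diffusion:
  d_clat: "13 um2/s"
seed: 0
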