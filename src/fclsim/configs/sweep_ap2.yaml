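# AP-2 number sweep at reference conditions; the sweep block lists the
# grid of AP-2 counts explored (10 - 400).
box_edge: "1 um"
dt: "3 us"
n_clathrin: 300
n_ap2: 100
duration: "30 min"
frame_interval: "0.1 s"
rates:
  k_cc_gated: "50x0.913 uM-1s-1"
  k_ap2_clat: "0.0012 uM-1s-1"
  koff_cc: "1 s-1"
  koff_ap2_clat: "1e-4 s-1"
diffusion:
  d_clat: "13 um2/s"
sweep:
  parameter: n_ap2
  values: [10, 50, 100, 150, 200, 300, 400]
seed: 0
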