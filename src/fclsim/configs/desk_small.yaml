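# Scaled-down desk configuration for invariant fuzzing and CI: half-size
# box, 60 clathrins, all rates x100, 5 simulated seconds.
box_edge: "0.5 um"
dt: "3 us"
n_clathrin: 60
n_ap2: 40
duration: "5 s"
frame_interval: "50 ms"
rates:
  k_cc_gated: "100x45.65 uM-1s-1"
  k_ap2_clat: "100x0.0012 uM-1s-1"
  koff_cc: "100 s-1"
  koff_ap2_clat: "100x1e-4 s-1"
diffusion:
  d_clat: "13 um2/s"
seed: 0
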