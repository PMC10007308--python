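# Example run configuration (small grids for quick turnaround).
# Full-scale instrument defaults apply to any omitted field:
#   tds: 80x90 px, 16x18 mm, 630 ms/px, 0.2-4 THz, 8 deg, 90 dB DR
#   lfi: 500x500 px, 25x25 mm, 0.1 ms/px, 2.71 THz, 600 MHz sweep, C=0.3
phantom:
  preset: parallel_venation
  shape: [40, 45]
  seed: 2
curve:
  t_fast_end: 20.0
  t_plateau_end: 120.0
tds:
  grid: [40, 45]
  extent_mm: [8.0, 9.0]
lfi:
  grid: [40, 45]
  extent_mm: [2.0, 2.25]
  samples_per_pulse: 128
water_anchors:
  - [2.71, 500.0]
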