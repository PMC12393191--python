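# Desk-scale simulation protocol: same echo train as the phantom session but
# on a 64 x 64 matrix.
schema_version: 1
tr: 1200.0
n_slices: 8
n_echoes: 64
n_shifted: 21
te1: 3.0
dte: 1.47
dpe: 0.8
K: 10.0
flip_angle: 75.0
slice_thickness: 2.0
readout_bandwidth: 800.0
matrix: [64, 64]
fov_read: 240.0
navigator_slots: [16, 49]
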