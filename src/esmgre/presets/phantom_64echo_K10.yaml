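# Phantom-session protocol: TR 1200 ms, flip 75 deg, 64 echoes with one third
# shifted, K = 10, full 240 x 216 matrix.
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
matrix: [240, 216]
fov_read: 240.0
navigator_slots: [16, 49]
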