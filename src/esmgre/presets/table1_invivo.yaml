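# In vivo ES-mGRE protocol: 64 echoes (43 prompt + 21 shifted), K = 10,
# navigators at train slots 16 and 49.
schema_version: 1
tr: 3000.0
n_slices: 23
n_echoes: 64
n_shifted: 21
te1: 3.0
dte: 1.47
dpe: 0.8
K: 10.0
flip_angle: 60.0
slice_thickness: 2.0
readout_bandwidth: 800.0
matrix: [240, 240]
fov_read: 240.0
navigator_slots: [16, 49]
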