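# Default soil profile: 30 x 5 cm layers, total available water capacity 177 mm
layer_thickness_m: 0.05
n_layers: 30
awc_total_mm: 177.0
max_root_depth_m: 1.5
lambda_surface: 1.0
lambda_bottom: 0.9
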