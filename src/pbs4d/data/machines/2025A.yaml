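# First operating point of the next-generation synchrotron (2025A).
name: "2025A"
scan_speed_x_max_energy: 8.0
scan_speed_y_max_energy: 20.0
max_energy: 230.0
magnet_prep_time: 0.0019
spill_change_time: 2.0
max_mu_per_spill: 30.0
max_mee_layers_per_spill: 16
recapture_efficiency: 0.8
mee_layer_switch_time: 0.2
beam_current: 30.0
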