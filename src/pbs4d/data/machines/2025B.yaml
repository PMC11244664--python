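# Most advanced operating point of the next-generation synchrotron (2025B).
# "unlimited" means the number of MEE layers per spill is never the binding
# constraint; spills end only when the MU ledger is exhausted.
name: "2025B"
scan_speed_x_max_energy: 40.0
scan_speed_y_max_energy: 120.0
max_energy: 230.0
magnet_prep_time: 0.0011
spill_change_time: 2.0
max_mu_per_spill: 60.0
max_mee_layers_per_spill: unlimited
recapture_efficiency: 1.0
mee_layer_switch_time: 0.1
beam_current: 40.0
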