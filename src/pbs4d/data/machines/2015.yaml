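# Hitachi synchrotron operating point in clinical service since 2015.
# Units: speeds m/s (at max_energy), times s, MU budgets in monitor units,
# beam_current MU/s, recapture_efficiency dimensionless fraction.
name: "2015"
scan_speed_x_max_energy: 6.0
scan_speed_y_max_energy: 10.0
max_energy: 230.0
magnet_prep_time: 0.0019
spill_change_time: 2.0
max_mu_per_spill: 20.0
max_mee_layers_per_spill: 4
recapture_efficiency: 0.5
mee_layer_switch_time: 0.2
beam_current: 8.0
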