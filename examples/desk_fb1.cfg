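# gutabm run manifest
k_ps_to_acetate_1 = 0.16
k_ps_to_acetate_2 = 0.16
k_psgut_to_acetate_1 = 0.16
k_psgut_to_acetate_2 = 0.0
k_ps_to_propionate_1 = 0.0
k_ps_to_propionate_2 = 0.26
k_acetate_to_butyrate_1 = 0.31
k_acetate_to_butyrate_2 = 0.0
k_toxin1 = 0.31
k_antitoxin1 = 0.1
k_antitoxin2 = 0.1
sensitive_toxin1_1 = inf
sensitive_toxin1_2 = 1.0
sensitive_toxin2_1 = 2.0
sensitive_toxin2_2 = 2.0
sensitive_antibiotic_1 = 2.0
sensitive_antibiotic_2 = 2.0
k_gut_out = 0.02
k_intake = 40.0
k_ps_mucus = 1.0
k_trans_mct = 8.3
km_acetate_mct = 15.0
km_propionate_mct = 15.0
km_butyrate_mct = 21.3
km_acetate_conv = 15.0
km_propionate_conv = 15.0
km_butyrate_conv = 21.3
search_radius_R = 3500.0
bacterial_speed = 7000.0
eat_period = 8.0
eat_range_multiplier_n = 3.0
contact_radius = 100.0
division_threshold = 4.0
initial_bacteria_1 = 400
initial_bacteria_2 = 400
initial_resistant_fraction = 0.0
initial_ps = 1200
initial_acetate = 200
initial_propionate = 200
initial_butyrate = 200
gut_length_L = 150000.0
gut_width_D = 30000.0
tick_hours = 0.02
particle_quantum = 1.0
jitter_step = 600.0
conc_grid_nx = 20
conc_grid_ny = 10
conc_mM_per_quantum = 3.0
enabled = FB1
fb1_toxin_percentage = 30.0
fb1_rate = 0.31
fb2_abundance_threshold = 100.0
fb3_abundance_threshold = 50.0
fb4_scfa_difference_threshold = 100.0
fb4_sense = propionate-butyrate
fb5_butyrate_threshold = 30.0
fb6_propionate_threshold = 100.0
fb7_butyrate_threshold = 300.0
gut_toxin_rate = 60.0
fb7_ps_rate = 30.0
orientation_inverted = false
k_ant_intake = 0.0
gavages_per_day = 1
course_days = 3.0
course_start = 0.0
gavage_duration = 1.0
retardation_constant_Rc = 2.0
mutation_rate_scale_alpha = 0.5
rng_seed = 1
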