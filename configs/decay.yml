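paradigm: DECAY
denitrification_enabled: false
scenario: preindustrial
seed: 0
spinup_check_years: 100
spinup_max_years: 3000
spinup_tol_per_century: 0.001
steps_per_year: 365
ramp_amplitude_degC: 3.0
ramp_exponent: 2.0
ramp_mixing_reduction: 0.5
ramp_year_end: 2150
ramp_year_start: 1800
C_d: 0.33
J_O_max: 0.5
T_min_diaz: 15.0
assim_zoo: 0.3
chl_per_N: 1.59
clip_epsilon: 1.0e-06
excret_zoo: 0.4
f_denit: 0.38
holling_saturation: false
k_N: 0.7
k_P: 0.04375
k_P_d: 0.04375
k_denit: 0.5
k_graze: 0.5
kh_deep: 5.0e-08
kh_surf: 0.0
mort_deep: 0.03
mort_phyto: 0.01
mort_zoo: 0.004
mort_zoo2: 0.0025
mu_max: 0.4
r_CN: 6.625
r_NP: 16.0
remin_deep: 0.01
remin_surf: 0.07
theta_d: 0.3
theta_det: 0.1
theta_o: 0.3
w_sink: 6.0
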