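format_version: 1
ros_basal_production: 0.012
ros_age_production: 0.194
ros_mito_coupling: 0.95
ros_tau_coupling: 1.4
ros_tau_saturation: 0.8
ros_clearance_basal: 5.0
ros_clearance_weight_sod2: 0.2
ros_clearance_weight_skn1: 0.16
ros_clearance_weight_daf16: 0.16
tau_production_basal: 0.09
tau_scenario_multiplier: 1.0
tau_ros_boost: 1.4
tau_ros_K: 1.21
tau_ros_n: 2.0
tau_clearance_basal: 0.03
tau_clearance_weight_bec1: 0.12
tau_clearance_weight_uprer: 0.36
vuln_ros_threshold: 1.66
vuln_tau_threshold: 0.3
death_hazard: 0.7
mito_damage_rate: 0.35
mito_damage_K: 0.55
mito_damage_n: 2.0
mitophagy_rate: 2.0
mito_biogenesis_decline: 0.04
mito_tau_damage_rate: 0.6
mito_tau_damage_K: 1.3
mito_tau_damage_n: 2.0
mito_uprmt_protection: 0.6
uprmt_basal_drive: 0.22
uprmt_relaxation_time: 0.5
uprmt_capacity_decline: 0.008
uprmt_expression_scale: 1.0
uprmt_ros_weight: 0.0
uprmt_ros_K: 0.5
uprmt_ros_n: 2.0
uprmt_mito_weight: 0.3
uprmt_mito_K: 0.35
uprmt_mito_n: 2.0
uprmt_self_weight: 0.62
uprmt_self_K: 0.45
uprmt_self_n: 6.0
uprmt_ros_stress_K: 2.22
uprmt_ros_stress_n: 4.0
uprmt_tau_stress_K: 4.2
uprmt_tau_stress_n: 6.0
uprmt_er_support_floor: 0.7
uprmt_er_support_K: 0.45
uprmt_er_support_n: 4.0
uprer_basal_drive: 0.53
uprer_relaxation_time: 0.5
uprer_capacity_decline: 0.006
uprer_bip_expression_scale: 1.0
uprer_ros_weight: 0.0
uprer_ros_K: 0.5
uprer_ros_n: 2.0
uprer_tau_weight: 0.1
uprer_tau_K: 0.5
uprer_tau_n: 2.0
uprer_self_weight: 0.35
uprer_self_K: 0.4
uprer_self_n: 4.0
uprer_ros_stress_K: 3.45
uprer_ros_stress_n: 4.0
uprer_tau_stress_K: 0.95
uprer_tau_stress_n: 6.0
uprer_flux_stress_K: 2.24
uprer_flux_stress_n: 6.0
pperk_basal_drive: 0.15
pperk_relaxation_time: 2.0
pperk_capacity_decline: 0.004
uprer_pperk_expression_scale: 1.0
pperk_ros_weight: 0.2
pperk_tau_weight: 0.45
skn1_basal_drive: 0.18
skn1_relaxation_time: 0.5
skn1_capacity_decline: 0.01
skn1_expression_scale: 1.0
skn1_ros_weight: 0.55
skn1_ros_K: 0.56
skn1_ros_n: 2.0
daf16_basal_drive: 0.15
daf16_relaxation_time: 0.5
daf16_capacity_decline: 0.008
daf16_expression_scale: 1.0
daf16_ros_weight: 0.6
daf16_ros_K: 0.63
daf16_ros_n: 2.0
sod2_basal_drive: 0.2
sod2_relaxation_time: 0.8
sod2_capacity_decline: 0.015
sod2_expression_scale: 1.0
sod2_skn1_weight: 0.45
sod2_skn1_K: 0.4
sod2_skn1_n: 2.0
sod2_daf16_weight: 0.35
sod2_daf16_K: 0.4
sod2_daf16_n: 2.0
bec1_basal_drive: 0.15
bec1_relaxation_time: 0.8
bec1_capacity_decline: 0.02
bec1_expression_scale: 1.0
bec1_skn1_weight: 0.3
bec1_skn1_K: 0.4
bec1_skn1_n: 2.0
bec1_daf16_weight: 0.25
bec1_daf16_K: 0.4
bec1_daf16_n: 2.0
bec1_mtor_weight: 0.3
bec1_mtor_K: 0.5
bec1_mtor_n: 2.0
mtor_basal_drive: 0.75
mtor_relaxation_time: 1.0
mtor_capacity_decline: 0.05
mtor_expression_scale: 1.0
pink1_basal_drive: 0.2
pink1_relaxation_time: 0.8
pink1_capacity_decline: 0.02
pink1_expression_scale: 1.0
pink1_skn1_weight: 0.3
pink1_skn1_K: 0.4
pink1_skn1_n: 2.0
pink1_daf16_weight: 0.3
pink1_daf16_K: 0.4
pink1_daf16_n: 2.0
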