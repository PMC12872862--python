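# Summary statistics (mean, SD) for a severe-aortic-stenosis TAVR cohort
# (n = 17 paired studies) at admission (baseline) and 3-month follow-up.
metric,baseline_mean,baseline_sd,followup_mean,followup_sd
stroke_work,13182,3234,8902,2249
potential_energy,11374,2900,7118,1743
global_work_index,3208,519,2353,475
global_constructive_work,3549,619,2696,469
global_wasted_work,128,58,132,74
global_work_efficiency,96.0,1.8,94.6,3.0
end_systolic_elastance,2.36,0.75,2.22,0.60
arterial_elastance,2.65,0.63,2.22,0.60
ventricular_efficiency,53.7,3.3,55.5,2.5
esp_over_edv,1.24,0.32,1.10,0.28
pmax_over_edv,1.28,0.33,1.13,0.29
ventriculo_arterial_coupling,1.17,0.22,1.01,0.18
pressure_volume_area,24556,5950,16020,3915
systolic_bp,159,28,159,17
mean_gradient,51,13,11,5
edv_3d,172,40,148,36
esv_3d,79,20,64,17
sv_3d,93,23,84,22
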