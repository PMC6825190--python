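patient_id,age_years,sex,site,lesion_area_cm2,photobleached_area_cm2
P1,62,F,left_posterior_buccal,0.871,3.94
P2,28,M,left_posterior_buccal,1.01,3.80
P3,40,M,right_anterior_buccal,1.62,3.93
P4,53,M,left_anterior_buccal,1.02,5.26
P5,45,M,left_anterior_buccal,1.55,7.69
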