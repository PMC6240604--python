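subject_id,group,pressure_mmhg,temperature_c,co_administered_ml,co_lost_ml,k_factor,cohb_pre,cohb_3,cohb_6,cohb_8,cohb_10,cohb_12,cohb_15,hb_g_dl,hct_pct,mchc_g_dl,body_mass_kg
subject_1,,,,32.3,0.0,0.934,1.35,,6.40,6.40,,,,,,,
subject_2,,,,42.5,0.0,0.923,0.90,,5.30,5.10,,,,,,,
subject_3,,,,82.9,0.0,0.931,0.85,,5.40,5.30,,,,,,,
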