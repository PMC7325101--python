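age_band,year,survey_n,population_n,prevalence_pct,ci_low_pct,ci_high_pct,printed_pct_change
35-44,2006,11287,13542328,10.8,9.8,11.9,
45-54,2006,7114,9820085,12.3,11.0,13.6,
55-64,2006,4594,6484080,14.4,12.8,16.1,
total,2006,22995,29846493,12.1,11.3,12.9,
35-44,2012,2783,15843461,16.3,13.7,19.2,51
45-54,2012,1995,11475090,14.9,12.4,17.8,21
55-64,2012,1495,8416371,16.6,13.5,20.1,15
total,2012,6273,35734922,15.9,14.2,17.7,31
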