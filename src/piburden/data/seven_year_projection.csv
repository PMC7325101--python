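outcome,base_count,base_se,unadjusted_increase,unadjusted_se,unadjusted_pct,adjusted_increase,adjusted_se,adjusted_pct
chd_incidence,1267400,9.7,10300,99.5,0.8,14200,122.1,1.1
stroke_incidence,293400,2.6,2200,19.2,0.8,3200,21.8,1.1
t2d_incidence,2586300,26.4,27100,155.1,1.0,34000,164,1.3
total_mi,294000,2.8,1500,17.5,0.5,2300,23.5,0.8
chd_mortality,141900,0.6,350,4.1,0.2,600,5.5,0.4
stroke_mortality,67000,0.5,400,3.7,0.6,600,4.2,0.9
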