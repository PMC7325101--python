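outcome,sex,rr,ci_low,ci_high,source
t2d,both,0.78,0.71,0.86,meta-analytic point estimate; CI synthetic default
stroke,both,0.80,0.72,0.89,meta-analytic point estimate; CI synthetic default
chd,male,0.86,0.77,0.96,meta-analytic point estimate; CI synthetic default
chd,female,0.76,0.67,0.86,meta-analytic point estimate; CI synthetic default
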