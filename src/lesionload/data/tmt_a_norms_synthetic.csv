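age_min,age_max,edu_min,edu_max,tmt_a_cutoff
18,39,0,11,38
18,39,12,30,35
40,59,0,11,45
40,59,12,30,41
60,79,0,11,58
60,79,12,30,52
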