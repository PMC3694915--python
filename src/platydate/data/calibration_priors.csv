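label,hypothesis,offset,mu_log,sigma_log,soft_min,soft_max
Root Haplorhini,shared,55.8,1.3,0.5,55.8,65.8
Catarrhini,shared,23.5,1.5,0.5,23.5,33.0
Hominini,shared,5.7,0.5,0.5,5.7,10.0
Cebinae,first,20.0,0.9,0.4,20.0,26.0
Aotinae,first,20.0,0.9,0.4,20.0,26.0
Cebinae,second,12.5,1.8,0.4,12.5,26.0
Aotinae,second,12.5,1.8,0.4,12.5,26.0
Cebinae,third,20.0,2.0,0.5,20.0,41.0
Aotinae,third,20.0,2.0,0.5,20.0,41.0
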