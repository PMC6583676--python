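study_id,formulation,n,duration_months,delta_active,delta_placebo
giordano,pCGS,60,3,0.135,-0.0742
herrero_beaumont,pCGS,210,6,0.0785,0.0315
reginster,pCGS,212,36,0.1606,0.1427
pavelka,pCGS,202,36,0.0487,0.0207
houpt,other_glucosamine,101,2,0.0293,0.0129
mcalindon,other_glucosamine,205,3,-0.0465,-0.0339
frestedt,other_glucosamine,35,3,0.1629,0.0613
chopra,other_glucosamine,70,3,0.0016,0.1232
cibere,other_glucosamine,137,6,0.0096,0.0006
clegg,other_glucosamine,630,6,0.0242,0.0383
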