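country_id,formulation,price_eur_per_day
AT,pCGS,0.82
BE,pCGS,0.74
CZ,pCGS,0.65
DE,pCGS,0.91
ES,pCGS,0.70
FR,pCGS,0.86
IT,pCGS,0.79
PL,pCGS,0.33
PT,pCGS,0.77
SE,pCGS,1.42
AT,other_glucosamine,0.58
BE,other_glucosamine,0.49
CZ,other_glucosamine,0.24
DE,other_glucosamine,0.66
ES,other_glucosamine,0.45
FR,other_glucosamine,0.61
IT,other_glucosamine,0.55
PL,other_glucosamine,0.21
PT,other_glucosamine,0.52
SE,other_glucosamine,1.05
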