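formulation,level,price_eur_per_day
pCGS,lowest,0.65
pCGS,median,0.79
pCGS,highest,0.88
other_glucosamine,lowest,0.45
other_glucosamine,median,0.55
other_glucosamine,highest,0.66
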