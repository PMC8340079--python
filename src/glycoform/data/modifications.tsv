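name	monoisotopic	average
carbamidomethyl	57.02146	57.052
oxidation	15.99491	15.999
deamidation	0.98402	0.984
water	18.01056	18.015
disulfide	-2.01565	-2.016
sodium_adduct	21.98194	21.982
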