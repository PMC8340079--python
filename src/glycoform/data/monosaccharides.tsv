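name	monoisotopic	average
Hex	162.05282	162.141
HexNAc	203.07937	203.194
Fuc	146.05791	146.142
Neu5Ac	291.09542	291.256
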