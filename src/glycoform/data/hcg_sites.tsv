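subunit	kind	start	end	capacity
hCG_alpha	N	52	52	1
hCG_alpha	N	78	78	1
hCG_beta	N	13	13	1
hCG_beta	N	30	30	1
hCG_beta	O	115	122	2
hCG_beta	O	123	133	2
hCG_beta	O	134	145	2
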