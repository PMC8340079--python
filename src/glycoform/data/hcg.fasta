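>hCG_alpha mature human chorionic gonadotropin alpha subunit (92 aa)
APDVQDCPECTLQENPFFSQPGAPILQCMGCCFSRAYPTPLRSKKTMLVQKNVTSESTCC
VAKSYNRVTVMGGFKVENHTACHCSTCYYHKS
>hCG_beta mature human chorionic gonadotropin beta subunit (145 aa)
SKEPLRPRCRPINATLAVEKEGCPVCITVNTTICAGYCPTMTRVLQGVLPALPQVVCNYR
DVRFESIRLPGCPRGVNPVVSYAVALSCQCALCRRSTTDCGGPKDHPLTCDDPRFQDSSS
SKAPPPSLPSPSRLPGPSDTPILPQ
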