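# Top 25 A2aR five-site variants ranked by naive -> PS4 enrichment rate
# in the FITC-APEC sort-seq screen (wild type TQWLH; loci T88 Q89 | W246
# L249 H250; wild-type enrichment rate 0.30).
variant	enrichment_rate
SLNIG	791
TSWIH	787
TTYLH	635
TGRIA	517
TTTLG	436
TLTLN	371
TGHIA	347
TSWLH	336
TGKLA	310
SLTLQ	244
TTWLS	231
TGKLS	224
TTWLH	193
TLYLN	178
TAWLH	149
TQYLG	148
TCWIH	142
TLMVH	122
TLWIH	121
MLNIG	118
TGRLG	114
SLNMG	109
TCWLH	100
TFWIN	96
TGRLS	91
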