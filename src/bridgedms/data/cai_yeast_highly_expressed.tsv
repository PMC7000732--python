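# Relative adaptiveness (w) of sense codons for Saccharomyces cerevisiae,
# derived from codon usage in the classic highly-expressed reference gene
# set; within each synonymous family the most frequent codon has w = 1.
# Stop codons are excluded (they never enter the CAI geometric mean).
codon	weight
TTT	0.113
TTC	1.000
TTA	0.117
TTG	1.000
CTT	0.006
CTC	0.003
CTA	0.039
CTG	0.003
ATT	0.823
ATC	1.000
ATA	0.003
ATG	1.000
GTT	1.000
GTC	0.831
GTA	0.002
GTG	0.004
TCT	1.000
TCC	0.693
TCA	0.036
TCG	0.005
AGT	0.021
AGC	0.031
CCT	0.047
CCC	0.009
CCA	1.000
CCG	0.002
ACT	0.921
ACC	1.000
ACA	0.012
ACG	0.006
GCT	1.000
GCC	0.316
GCA	0.015
GCG	0.001
TAT	0.071
TAC	1.000
CAT	0.245
CAC	1.000
CAA	1.000
CAG	0.007
AAT	0.053
AAC	1.000
AAA	0.135
AAG	1.000
GAT	0.554
GAC	1.000
GAA	1.000
GAG	0.016
TGT	1.000
TGC	0.077
TGG	1.000
CGT	0.063
CGC	0.004
CGA	0.002
CGG	0.002
AGA	1.000
AGG	0.003
GGT	1.000
GGC	0.020
GGA	0.002
GGG	0.004
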