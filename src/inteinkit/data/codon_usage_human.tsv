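residue	codon	frequency
A	GCT	0.26
A	GCC	0.40
A	GCA	0.23
A	GCG	0.11
R	CGT	0.08
R	CGC	0.19
R	CGA	0.11
R	CGG	0.21
R	AGA	0.20
R	AGG	0.21
N	AAT	0.46
N	AAC	0.54
D	GAT	0.46
D	GAC	0.54
C	TGT	0.45
C	TGC	0.55
Q	CAA	0.25
Q	CAG	0.75
E	GAA	0.42
E	GAG	0.58
G	GGT	0.16
G	GGC	0.34
G	GGA	0.25
G	GGG	0.25
H	CAT	0.41
H	CAC	0.59
I	ATT	0.36
I	ATC	0.48
I	ATA	0.16
L	TTA	0.07
L	TTG	0.13
L	CTT	0.13
L	CTC	0.20
L	CTA	0.07
L	CTG	0.40
K	AAA	0.42
K	AAG	0.58
M	ATG	1.00
F	TTT	0.45
F	TTC	0.55
P	CCT	0.28
P	CCC	0.33
P	CCA	0.27
P	CCG	0.12
S	TCT	0.18
S	TCC	0.22
S	TCA	0.15
S	TCG	0.06
S	AGT	0.15
S	AGC	0.24
T	ACT	0.24
T	ACC	0.36
T	ACA	0.28
T	ACG	0.12
W	TGG	1.00
Y	TAT	0.43
Y	TAC	0.57
V	GTT	0.18
V	GTC	0.24
V	GTA	0.11
V	GTG	0.47
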