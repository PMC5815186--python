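# miqs_synthetic.tsv -- SYNTHETIC stand-in for the MIQS amino-acid substitution
# matrix (the published MIQS file is not redistributable in this package).
# Constructed as 0.5*BLOSUM45 + 0.5*BLOSUM62, rounded to one decimal, to match
# MIQS's remote-homolog orientation. Float-valued, symmetric.
	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V	X
A	4.5	-1.5	-1.5	-2.0	-0.5	-1.0	-1.0	0.0	-2.0	-1.0	-1.0	-1.0	-1.0	-2.0	-1.0	1.0	0.0	-2.5	-2.0	0.0	0.0
R	-1.5	6.0	0.0	-1.5	-3.0	1.0	0.0	-2.0	0.0	-3.0	-2.0	2.5	-1.0	-2.5	-2.0	-1.0	-1.0	-2.5	-1.5	-2.5	-1.0
N	-1.5	0.0	6.0	1.5	-2.5	0.0	0.0	0.0	1.0	-2.5	-3.0	0.0	-2.0	-2.5	-2.0	1.0	0.0	-4.0	-2.0	-3.0	-1.0
D	-2.0	-1.5	1.5	6.5	-3.0	0.0	2.0	-1.0	-0.5	-3.5	-3.5	-0.5	-3.0	-3.5	-1.0	0.0	-1.0	-4.0	-2.5	-3.0	-1.0
C	-0.5	-3.0	-2.5	-3.0	10.5	-3.0	-3.5	-3.0	-3.0	-2.0	-1.5	-3.0	-1.5	-2.0	-3.5	-1.0	-1.0	-3.5	-2.5	-1.0	-2.0
Q	-1.0	1.0	0.0	0.0	-3.0	5.5	2.0	-2.0	0.5	-2.5	-2.0	1.0	0.0	-3.5	-1.0	0.0	-1.0	-2.0	-1.0	-2.5	-1.0
E	-1.0	0.0	0.0	2.0	-3.5	2.0	5.5	-2.0	0.0	-3.0	-2.5	1.0	-2.0	-3.0	-0.5	0.0	-1.0	-3.0	-2.0	-2.5	-1.0
G	0.0	-2.0	0.0	-1.0	-3.0	-2.0	-2.0	6.5	-2.0	-4.0	-3.5	-2.0	-2.5	-3.0	-2.0	0.0	-2.0	-2.0	-3.0	-3.0	-1.0
H	-2.0	0.0	1.0	-0.5	-3.0	0.5	0.0	-2.0	9.0	-3.0	-2.5	-1.0	-1.0	-1.5	-2.0	-1.0	-2.0	-2.5	2.0	-3.0	-1.0
I	-1.0	-3.0	-2.5	-3.5	-2.0	-2.5	-3.0	-4.0	-3.0	4.5	2.0	-3.0	1.5	0.0	-2.5	-2.0	-1.0	-2.5	-0.5	3.0	-1.0
L	-1.0	-2.0	-3.0	-3.5	-1.5	-2.0	-2.5	-3.5	-2.5	2.0	4.5	-2.5	2.0	0.5	-3.0	-2.5	-1.0	-2.0	-0.5	1.0	-1.0
K	-1.0	2.5	0.0	-0.5	-3.0	1.0	1.0	-2.0	-1.0	-3.0	-2.5	5.0	-1.0	-3.0	-1.0	-0.5	-1.0	-2.5	-1.5	-2.0	-1.0
M	-1.0	-1.0	-2.0	-3.0	-1.5	0.0	-2.0	-2.5	-1.0	1.5	2.0	-1.0	5.5	0.0	-2.0	-1.5	-1.0	-1.5	-0.5	1.0	-1.0
F	-2.0	-2.5	-2.5	-3.5	-2.0	-3.5	-3.0	-3.0	-1.5	0.0	0.5	-3.0	0.0	7.0	-3.5	-2.0	-1.5	1.0	3.0	-0.5	-1.0
P	-1.0	-2.0	-2.0	-1.0	-3.5	-1.0	-0.5	-2.0	-2.0	-2.5	-3.0	-1.0	-2.0	-3.5	8.0	-1.0	-1.0	-3.5	-3.0	-2.5	-1.5
S	1.0	-1.0	1.0	0.0	-1.0	0.0	0.0	0.0	-1.0	-2.0	-2.5	-0.5	-1.5	-2.0	-1.0	4.0	1.5	-3.5	-2.0	-1.5	0.0
T	0.0	-1.0	0.0	-1.0	-1.0	-1.0	-1.0	-2.0	-2.0	-1.0	-1.0	-1.0	-1.0	-1.5	-1.0	1.5	5.0	-2.5	-1.5	0.0	0.0
W	-2.5	-2.5	-4.0	-4.0	-3.5	-2.0	-3.0	-2.0	-2.5	-2.5	-2.0	-2.5	-1.5	1.0	-3.5	-3.5	-2.5	13.0	2.5	-3.0	-2.0
Y	-2.0	-1.5	-2.0	-2.5	-2.5	-1.0	-2.0	-3.0	2.0	-0.5	-0.5	-1.5	-0.5	3.0	-3.0	-2.0	-1.5	2.5	7.5	-1.0	-1.0
V	0.0	-2.5	-3.0	-3.0	-1.0	-2.5	-2.5	-3.0	-3.0	3.0	1.0	-2.0	1.0	-0.5	-2.5	-1.5	0.0	-3.0	-1.0	4.5	-1.0
X	0.0	-1.0	-1.0	-1.0	-2.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.0	-1.5	0.0	0.0	-2.0	-1.0	-1.0	-1.0
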