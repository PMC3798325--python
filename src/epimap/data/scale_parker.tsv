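# Parker, Guo & Hodges (1986) HPLC-derived hydrophilicity scale.
# Positive = hydrophilic (surface/antigenic tendency).
residue	value
A	2.1
R	4.2
N	7.0
D	10.0
C	1.4
Q	6.0
E	7.8
G	5.7
H	2.1
I	-8.0
L	-9.2
K	5.7
M	-4.2
F	-9.2
P	2.1
S	6.5
T	5.2
W	-10.0
Y	-1.9
V	-3.7
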