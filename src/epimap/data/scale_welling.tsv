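# Welling et al. (1985) antigenicity value: log ratio of residue frequency
# in known antigenic regions vs. average proteins. Positive = antigenic.
residue	value
A	0.115
R	0.058
N	-0.077
D	0.065
C	-0.120
Q	-0.011
E	-0.071
G	-0.184
H	0.312
I	-0.292
L	0.075
K	0.206
M	-0.385
F	-0.141
P	-0.053
S	-0.026
T	-0.045
W	-0.114
Y	0.013
V	-0.013
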