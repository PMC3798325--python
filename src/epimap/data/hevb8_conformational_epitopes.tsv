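# Published map of discontinuous (conformational) epitopes on the Hev b 8
# latex profilin (Hevea brasiliensis, UniProt Q9LEI8, PDB 1g5u chain A).
# Residue segments use author numbering: "start-end:SEQ" for a contiguous
# stretch, "pos:X" for a single residue; segments are ';'-joined.
# centers lists the central (protruding) residue(s) of each epitope.
epitope_id	centers	segments
1	2:S	2-10:SWQTYVDDH;35:Q;125:Y;129-131:QGL
2	19:R	8-10:DDH;13-21:CDIDGHRLT;37-38:SS;107-111:DEPLT
3	37:S;38:S	4:Q;8:D;19-21:RLT;32:V;35-41:QSSSFPQ;69:G;107:D
4	41:Q	30-32:GSV;35-45:QSSSFPQFKSD;66:H;69-70:GT
5	44:S;45:D	28-32:HDGSV;40-45:PQFKSD;48-52:AAVMK;63:T;66:H;69:G
6	63:T	45:D;48-49:AA;52:K;58-63:GSLAPT;66:H;69-74:GTKYMV
7	76:Q	57-58:PG;61:A;73-81:MVIQGEPGA;84-86:RGK;112:P;116:N;120:E
8	79:P	51-52:MK;55-59:DEPGS;74-81:VIQGEPGA;84:R;96:K;120:E
9	108:E	17-21:GHRLT;86-89:KKGS;107-112:DEPLTP
10	117:M	10:H;13-18:CDIDGH;84:R;111-113:TPG;116-117:NM;120-121:ER;124-125:DY
11	128:D	6:Y;96-99:KTGQ;120-121:ER;124-131:DYLLDQGL
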