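# ECIF ligand atom-type vocabulary (70 environment types, one per line,
# lexicographic order). Curated reconstruction covering drug-like
# chemistry; see docs/methods.md for provenance and conventions.
B;3;3;0;0;0
Br;1;1;0;0;0
C;3;3;0;1;1
C;4;1;1;0;0
C;4;1;2;0;0
C;4;1;3;0;0
C;4;2;0;0;0
C;4;2;1;0;0
C;4;2;1;0;1
C;4;2;1;1;1
C;4;2;2;0;0
C;4;2;2;0;1
C;4;3;0;0;0
C;4;3;0;0;1
C;4;3;0;1;1
C;4;3;1;0;0
C;4;3;1;0;1
C;4;4;0;0;0
C;4;4;0;0;1
C;5;3;0;0;0
Cl;1;1;0;0;0
F;1;1;0;0;0
I;1;1;0;0;0
N;3;1;0;0;0
N;3;1;1;0;0
N;3;1;2;0;0
N;3;2;0;0;0
N;3;2;0;0;1
N;3;2;0;1;1
N;3;2;1;0;0
N;3;2;1;0;1
N;3;2;1;1;1
N;3;3;0;0;0
N;3;3;0;0;1
N;3;3;0;1;1
N;4;1;2;0;0
N;4;1;3;0;0
N;4;2;1;0;0
N;4;2;1;1;1
N;4;2;2;0;0
N;4;2;2;0;1
N;4;3;0;0;0
N;4;3;0;0;1
N;4;3;1;0;0
N;4;3;1;0;1
N;4;4;0;0;0
N;4;4;0;0;1
N;5;2;0;0;0
N;5;3;0;0;0
O;1;1;0;0;0
O;2;1;0;0;0
O;2;1;1;0;0
O;2;2;0;0;0
O;2;2;0;0;1
O;2;2;0;1;1
P;5;3;0;0;0
P;5;4;0;0;0
P;5;4;0;0;1
P;6;4;0;0;0
S;1;1;0;0;0
S;2;1;0;0;0
S;2;1;1;0;0
S;2;2;0;0;0
S;2;2;0;0;1
S;2;2;0;1;1
S;3;3;0;0;0
S;4;3;0;0;0
S;6;4;0;0;0
S;6;4;0;0;1
S;7;4;0;0;0
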