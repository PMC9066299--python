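# ECIF protein atom-type vocabulary: the 22 distinct environment types
# realized by the standard amino-acid topology templates (see docs/methods.md).
C;4;1;3;0;0
C;4;2;1;1;1
C;4;2;2;0;0
C;4;2;2;0;1
C;4;3;0;0;0
C;4;3;0;1;1
C;4;3;1;0;0
C;4;3;1;0;1
C;6;3;0;0;0
N;3;1;2;0;0
N;3;2;0;1;1
N;3;2;1;0;0
N;3;2;1;1;1
N;3;3;0;0;1
N;4;1;2;0;0
N;4;1;3;0;0
N;4;2;1;0;0
O;1;1;0;0;0
O;2;1;0;0;0
O;2;1;1;0;0
S;2;1;1;0;0
S;2;2;0;0;0
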