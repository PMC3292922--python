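# Neuronal-expression flags for the overlapping regulators; `original` preserves the
# curated spelling before normalization to {yes, no, unknown}.
gene	neuronal_expression	original	provenance
Y53C10A.12	yes	yes	overlap row 1
F26D10.3	yes	yes	overlap row 2
F54D5.8	unknown	?	overlap row 3
K01C8.10	yes	yes	overlap row 4
C07G2.3	unknown	?	overlap row 5
T09B4.10	yes	yes	overlap row 6
Y94H6A.6	unknown	?	overlap row 7
M7.1	yes	yes	overlap row 8
C06A1.1	yes	Yes	overlap row 9
F52D10.3	yes	yes	overlap row 10
M117.2	yes	yes	overlap row 10
C39F7.4	yes	yes	overlap row 11
B0361.10	unknown	?	overlap row 12
C54H2.5	yes	yes	overlap row 13
Y54E2A.12	unknown	?	overlap row 14
R11A8.4	yes	Yes	overlap row 15
C53A5.3	no	No?	overlap row 16
F02E9.4	yes	yes	overlap row 17
F59F4.1	unknown	?	overlap row 18
ZK256.1	yes	yes	overlap row 19
W08D2.5	unknown	?	overlap row 20
Y43F4B.4	yes	yes	overlap row 21
F49E10.5	unknown	?	overlap row 22
K08F8.6	yes	yes	overlap row 23
T17E9.1	yes	yes	overlap row 24
H18N23.2	unknown	?	overlap row 25
T14F9.1	yes	Yes	overlap row 26
T21E12.4	yes	Yes	overlap row 27
Y113G7B.18	unknown	?	overlap row 28
Y116A8C.35	yes	Yes	overlap row 29
F56C11.1	no	No	overlap row 30
C32E8.10	yes	Yes	overlap row 31
JC8.10	yes	Yes	overlap row 32
ZK742.1	unknown	?	overlap row 33
C05C8.7	no	No	overlap row 34
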