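gene	n_cancer_types	n_partners	n_breakpoints	obs
RARA	1	1	1	15
RUNX1T1	1	1	1	7
PML	1	1	3	16
ERG	2	3	2	24
RUNX1	1	2	2	8
SFPQ	1	1	2	3
TFE3	1	1	2	3
TRPS1	1	4	1	4
YY1	1	2	1	2
BPTF	1	2	3	3
GLIS3	2	2	1	2
IKBKB	1	2	2	2
KAT6A	2	2	1	2
NCOR1	1	2	2	2
RFWD2	1	2	2	2
WWP1	1	2	2	2
BRIP1	1	2	2	2
ARID1B	2	2	1	2
RBMS1	2	1	2	2
PAX8	1	2	2	2
UHRF1	2	2	1	2
ZNF143	2	2	1	2
FOXK2	1	3	3	3
NFIX	2	3	2	3
RFX4	2	3	2	3
CLOCK	2	2	2	2
KHSRP	2	2	2	2
NFIB	2	2	2	2
TRIM24	2	2	2	2
YAP1	2	2	2	2
ZBTB48	2	2	2	2
FGFR1	2	2	2	2
LIN28A	2	2	2	2
ETV6	3	3	5	10
MLLT10	2	3	6	7
EP300	2	3	3	3
TBL1XR1	2	3	3	3
VAV1	2	3	3	3
KDM5A	2	4	4	4
NCOR2	3	3	3	3
SMARCA4	3	3	3	3
SND1	4	4	5	6
KDM4B	5	5	3	5
NSD1	4	5	5	6
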