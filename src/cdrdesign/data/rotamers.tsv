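restype	chi1	chi2	chi3	chi4	frequency
ALA	.	.	.	.	1.00
GLY	.	.	.	.	1.00
PRO	.	.	.	.	1.00
SER	62	.	.	.	0.48
SER	-177	.	.	.	0.22
SER	-65	.	.	.	0.29
CYS	-65	.	.	.	0.50
CYS	-177	.	.	.	0.26
CYS	62	.	.	.	0.23
THR	62	.	.	.	0.49
THR	-175	.	.	.	0.07
THR	-65	.	.	.	0.43
VAL	175	.	.	.	0.73
VAL	-60	.	.	.	0.20
VAL	63	.	.	.	0.06
ILE	-65	170	.	.	0.60
ILE	-57	-60	.	.	0.13
ILE	62	170	.	.	0.10
ILE	-177	166	.	.	0.08
LEU	-65	175	.	.	0.59
LEU	177	65	.	.	0.29
LEU	-85	65	.	.	0.02
MET	-65	-65	-70	.	0.19
MET	-65	175	75	.	0.15
MET	-65	175	180	.	0.13
MET	-177	180	75	.	0.10
PHE	-65	-85	.	.	0.44
PHE	-65	-30	.	.	0.09
PHE	177	80	.	.	0.33
PHE	62	90	.	.	0.13
TYR	-65	-85	.	.	0.43
TYR	-65	-30	.	.	0.09
TYR	177	80	.	.	0.34
TYR	62	90	.	.	0.13
TRP	-65	-90	.	.	0.11
TRP	-65	95	.	.	0.32
TRP	177	-105	.	.	0.16
TRP	62	-90	.	.	0.11
HIS	-65	-70	.	.	0.29
HIS	177	-165	.	.	0.14
HIS	62	-75	.	.	0.13
ASP	-70	-15	.	.	0.51
ASP	-177	0	.	.	0.21
ASP	62	10	.	.	0.16
ASN	-65	-20	.	.	0.39
ASN	-177	30	.	.	0.14
ASN	62	-20	.	.	0.13
GLU	-65	180	-10	.	0.26
GLU	177	180	0	.	0.13
GLU	-65	-65	-40	.	0.12
GLN	-65	180	-25	.	0.23
GLN	177	180	20	.	0.12
GLN	-65	-65	-40	.	0.11
LYS	-65	180	180	180	0.25
LYS	180	180	180	180	0.16
LYS	-65	-68	180	180	0.09
ARG	-67	180	180	180	0.14
ARG	180	180	180	180	0.11
ARG	-67	180	-65	-85	0.07
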