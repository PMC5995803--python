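gene	cell	rank
AQP4	AST	1
GFAP	AST	2
SLC1A2	AST	3
SLC1A3	AST	4
GJA1	AST	5
ALDH1L1	AST	6
SOX9	AST	7
MLC1	AST	8
CLDN5	END	1
FLT1	END	2
PECAM1	END	3
VWF	END	4
SLC2A1	END	5
TEK	END	6
ESAM	END	7
OCLN	END	8
CSF1R	MIC	1
CX3CR1	MIC	2
P2RY12	MIC	3
AIF1	MIC	4
TMEM119	MIC	5
ITGAM	MIC	6
TYROBP	MIC	7
C1QB	MIC	8
SNAP25	NEU	1
SYT1	NEU	2
RBFOX3	NEU	3
STMN2	NEU	4
GAD1	NEU	5
SLC17A7	NEU	6
NEFL	NEU	7
SYN1	NEU	8
PLP1	MOL	1
MBP	MOL	2
MOG	MOL	3
MAG	MOL	4
UGT8	MOL	5
ERMN	MOL	6
CNP	MOL	7
MOBP	MOL	8
PDGFRA	OPC	1
CSPG4	OPC	2
OLIG1	OPC	3
OLIG2	OPC	4
SOX10	OPC	5
GPR17	OPC	6
VCAN	OPC	7
LHFPL3	OPC	8
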