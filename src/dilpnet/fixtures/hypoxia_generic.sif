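# Generic myeloma signaling map, hypoxia contrast.
# Best-effort transcription of the published pathway diagram: 31 proteins,
# 42 reactions adding fibronectin/integrin/FAK adhesion signaling, EGFR/PLC/
# PKC, E-cadherin/beta-catenin and YAP to the core growth/apoptosis modules.
HIF1A	activate	FN1
FN1	activate	ITGB1
ITGB1	activate	FAK
FAK	activate	SRC
FAK	activate	PI3K
FAK	activate	JNK
SRC	activate	RAS
EGFR	activate	PI3K
EGFR	activate	RAS
EGFR	activate	PLCG
PLCG	activate	PKC
PDK1	activate	PKC
PI3K	activate	PDK1
PDK1	activate	AKT
PI3K	activate	AKT
AKT	activate	MTOR
MTOR	activate	P70S6K
P70S6K	activate	S6
AKT	activate	IKK
IKK	activate	NFKB
PKC	activate	NFKB
RAS	activate	RAF
PKC	activate	RAF
RAF	activate	MEK
MEK	activate	ERK
ERK	activate	CMYC
JNK	activate	CJUN
CJUN	activate	CMYC
ECADHERIN	inhibit	CTNNB
CTNNB	activate	CMYC
ECADHERIN	inhibit	PI3K
ECADHERIN	activate	YAP
YAP	inhibit	CMYC
HIF1A	activate	P53
AKT	inhibit	P53
P53	activate	P21
P53	activate	BAX
NFKB	activate	BCL2
BCL2	inhibit	BAX
AKT	inhibit	BAX
ERK	inhibit	BIM
BIM	activate	BAX
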