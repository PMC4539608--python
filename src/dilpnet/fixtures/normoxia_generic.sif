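# Generic myeloma signaling map, normoxic co-culture contrast.
# Best-effort transcription of the published pathway diagram: 31 proteins,
# 45 reactions covering receptor -> PI3K/AKT/mTOR, RAS/MEK/ERK, JAK/STAT,
# NF-kB, JNK/c-Jun, p53/p21 and the mitochondrial apoptosis module.
VEGFR	activate	PI3K
EGFR	activate	PI3K
ERBB2_ERBB3	activate	PI3K
EGFR	activate	RAS
ERBB2_ERBB3	activate	RAS
VEGFR	activate	RAS
PI3K	activate	PDK1
PDK1	activate	AKT
PI3K	activate	AKT
AKT	activate	MTOR
AMPK	inhibit	MTOR
MTOR	activate	P70S6K
ERK	activate	P70S6K
P70S6K	activate	S6
AKT	activate	IKK
IKK	activate	NFKB
AKT	activate	FOXO3
AKT	inhibit	BAD
AKT	inhibit	BAX
AKT	inhibit	P53
RAS	activate	RAF
RAF	activate	MEK
MEK	activate	ERK
ERK	activate	CMYC
ERK	inhibit	BIM
JAK	activate	STAT3
STAT3	activate	CMYC
STAT3	activate	MCL1
STAT3	activate	BCL2
NFKB	activate	BCL2
NFKB	activate	CMYC
NFKB	activate	MCL1
JNK	activate	CJUN
ERK	activate	CJUN
CJUN	activate	CMYC
AMPK	activate	P53
P53	activate	P21
P53	activate	BAX
FOXO3	activate	BIM
CASP8	activate	CASP3
BAX	activate	CASP3
BIM	activate	BAX
BCL2	inhibit	BAX
MCL1	inhibit	BIM
BAD	inhibit	BCL2
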