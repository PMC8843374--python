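protein_id	target_pdb	residue	mechanisms
adk	1ake	136	KAT:YfiQ;KAT:YiaC
adk	1ake	141	AcP
adk	1ake	145	AcP
adk	1ake	157	AcP
adk	1ake	192	AcP
adk	1ake	211	AcP
icd	1ai2	4	KAT:YiaC;AcP
icd	1ai2	12	AcP
icd	1ai2	174	AcP
icd	1ai2	177	AcP
icd	1ai2	235	AcP
icd	1ai2	265	AcP
icd	1ai2	378	KAT:YiaC
katE	1cf9	56	KAT:YfiQ;KAT:YiaC
katE	1cf9	64	KAT:YfiQ
fmt	2fmt	45	KAT:YfiQ;KAT:YiaC
fmt	2fmt	46	KAT:YfiQ;KAT:YiaC
yaaA	5caj	55	KAT:YfiQ;KAT:YiaC
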