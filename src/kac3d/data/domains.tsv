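protein_id	domain	ranges
adk	CORE	1-29,60-121,160-214
adk	AMP-binding	30-59
adk	LID	122-159
icd	large	1-124,321-416
icd	small	125-162,200-320
icd	clasp	163-199
katE	N-terminal arm	1-127
katE	beta-barrel	128-390
katE	wrapping loop	391-504
katE	alpha-helical	505-564
katE	C-terminal	600-753
fmt	Rossmann	1-189
fmt	Loop1	34-49
fmt	linker	190-208
fmt	OB-fold	209-314
yaaA	HhH	35-66
yaaA	beta-strand motif	187-202,239-258
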