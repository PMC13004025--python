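pattern	name	anchor_cterm	min_membrane_distance
L@@L	LxxL	false	15
N@@Y	NxxY	false
[FYW]@[LMV]	FYWxLMV	false
[GAVCPLIMWF]@[FYV]@[FY]	PhixFYVxFY	false
[DE][ST]@[GAVCPLIMWF]	PDZ	true
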