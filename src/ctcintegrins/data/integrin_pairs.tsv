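alpha	beta
ITGA1	ITGB1
ITGA10	ITGB1
ITGA11	ITGB1
ITGA2	ITGB1
ITGA2B	ITGB3
ITGA3	ITGB1
ITGA4	ITGB1
ITGA4	ITGB7
ITGA5	ITGB1
ITGA6	ITGB1
ITGA6	ITGB4
ITGA7	ITGB1
ITGA8	ITGB1
ITGA9	ITGB1
ITGAD	ITGB2
ITGAE	ITGB7
ITGAL	ITGB2
ITGAM	ITGB2
ITGAV	ITGB1
ITGAV	ITGB3
ITGAV	ITGB5
ITGAV	ITGB6
ITGAV	ITGB8
ITGAX	ITGB2
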