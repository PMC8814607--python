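name	recognition	cut_top	cut_bottom
CsiI	ACCWGGT	1	6
XmaJI	CCTAGG	1	5
SacI	GAGCTC	5	1
NcoI	CCATGG	1	5
SdaI	CCTGCAGG	6	2
ScaI	AGTACT	3	3
AarI	CACCTGC	11	15
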