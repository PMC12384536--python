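cell_line	group	day	colony_count
AFs1#	AF	10	125
AFs1#	AF	14	183
AFs1#	AF	18	220
AFs2#	AF	10	86
AFs2#	AF	14	110
AFs2#	AF	18	166
PFs1#	PF	10	0
PFs1#	PF	14	4
PFs1#	PF	18	12
PFs2#	PF	10	5
PFs2#	PF	14	19
PFs2#	PF	18	25
PFs3#	PF	10	5
PFs3#	PF	14	14
PFs3#	PF	18	19
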