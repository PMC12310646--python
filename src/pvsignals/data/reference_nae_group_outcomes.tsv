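group	reports	deaths
IMMUNE_MYOPATHY	1845	518
MG_SPECTRUM	1319	404
AIE	489	99
GBS_SPECTRUM	389	75
ASEPTIC_MENINGITIS	251	9
MYELITIS	140	22
CIDP	51	1
NMOSD	26	3
CNS_VASCULITIS	22	2
MOGAD	6	1
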