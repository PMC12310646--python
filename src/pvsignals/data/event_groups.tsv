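pt	group	nae_flag
autoimmune encephalitis	AIE	1
autoimmune encephalopathy	AIE	1
encephalitis autoimmune	AIE	1
immune-mediated encephalitis	AIE	1
noninfective encephalitis	AIE	1
guillain-barre syndrome	GBS_SPECTRUM	1
miller fisher syndrome	GBS_SPECTRUM	1
acute motor axonal neuropathy	GBS_SPECTRUM	1
acute motor-sensory axonal neuropathy	GBS_SPECTRUM	1
chronic inflammatory demyelinating polyradiculoneuropathy	CIDP	1
immune-mediated myasthenia gravis	MG_SPECTRUM	1
myasthenia gravis	MG_SPECTRUM	1
myasthenia gravis crisis	MG_SPECTRUM	1
myasthenic syndrome	MG_SPECTRUM	1
ocular myasthenia	MG_SPECTRUM	1
autoimmune myositis	IMMUNE_MYOPATHY	1
dermatomyositis	IMMUNE_MYOPATHY	1
immune-mediated myositis	IMMUNE_MYOPATHY	1
myositis	IMMUNE_MYOPATHY	1
necrotizing myositis	IMMUNE_MYOPATHY	1
polymyositis	IMMUNE_MYOPATHY	1
immune-mediated myelitis	MYELITIS	1
myelitis	MYELITIS	1
myelitis transverse	MYELITIS	1
noninfectious myelitis	MYELITIS	1
neuromyelitis optica spectrum disorder	NMOSD	1
acute disseminated encephalomyelitis	ADEM	1
multiple sclerosis	MULTIPLE_SCLEROSIS	1
primary progressive multiple sclerosis	MULTIPLE_SCLEROSIS	1
progressive multiple sclerosis	MULTIPLE_SCLEROSIS	1
progressive relapsing multiple sclerosis	MULTIPLE_SCLEROSIS	1
relapsing multiple sclerosis	MULTIPLE_SCLEROSIS	1
relapsing-remitting multiple sclerosis	MULTIPLE_SCLEROSIS	1
secondary progressive multiple sclerosis	MULTIPLE_SCLEROSIS	1
myelin oligodendrocyte glycoprotein antibody-associated disease	MOGAD	1
meningitis aseptic	ASEPTIC_MENINGITIS	1
meningitis noninfective	ASEPTIC_MENINGITIS	1
central nervous system vasculitis	CNS_VASCULITIS	1
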