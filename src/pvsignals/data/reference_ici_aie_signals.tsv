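database	drug	n	ror	ror_lo	ror_hi	prr	chi2	ebgm	ebgm05	ic	ic025
FAERS	pembrolizumab	166	33.79	28.83	39.61	33.76	4841.34	31.05	27.19	4.96	4.72
FAERS	nivolumab	158	26.53	22.55	31.21	26.51	3573.71	24.5	21.39	4.61	4.38
FAERS	atezolizumab	87	44.57	35.95	55.26	44.5	3539.63	42.62	35.6	5.41	5.1
FAERS	ipilimumab	47	29.22	21.88	39.03	29.19	1249.64	28.53	22.39	4.83	4.41
FAERS	durvalumab	23	25.04	16.6	37.78	25.02	524.34	24.75	17.54	4.63	4.04
JADER	nivolumab	147	12.67	10.45	15.35	12.63	1115.79	9.24	7.62	3.21	1.54
JADER	pembrolizumab	113	12.73	10.33	15.7	12.7	944.92	10.07	8.17	3.33	1.66
JADER	ipilimumab	94	11.65	9.31	14.58	11.62	742.36	9.64	7.7	3.27	1.6
JADER	atezolizumab	50	13.84	10.33	18.55	13.79	534.42	12.52	9.34	3.65	1.98
JADER	durvalumab	23	9.33	6.13	14.18	9.3	162.67	8.92	5.87	3.16	1.49
JADER	tremelimumab	5	7.15	2.96	17.28	7.14	26.14	7.08	2.93	2.82	1.15
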