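drug	nae_reports	deaths
ipilimumab	362	61
pembrolizumab	1325	325
nivolumab	1490	365
cemiplimab	60	19
atezolizumab	496	106
durvalumab	200	57
avelumab	66	13
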