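drug	nae_reports	total_reports
cemiplimab	60	1959
avelumab	66	2165
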