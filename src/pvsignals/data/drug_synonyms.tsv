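ingredient	synonym
ipilimumab	ipilimumab
ipilimumab	yervoy
pembrolizumab	pembrolizumab
pembrolizumab	keytruda
pembrolizumab	lambrolizumab
nivolumab	nivolumab
nivolumab	opdivo
cemiplimab	cemiplimab
cemiplimab	cemiplimab-rwlc
cemiplimab	libtayo
atezolizumab	atezolizumab
atezolizumab	tecentriq
durvalumab	durvalumab
durvalumab	imfinzi
avelumab	avelumab
avelumab	bavencio
tremelimumab	tremelimumab
tremelimumab	imjudo
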