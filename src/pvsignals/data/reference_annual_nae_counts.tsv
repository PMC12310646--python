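year	nae	other	total
2007	0	2	2
2008	0	5	5
2009	1	9	10
2010	0	2	2
2011	4	284	288
2012	6	1052	1058
2013	3	989	992
2014	15	1794	1809
2015	49	4490	4539
2016	137	9240	9377
2017	219	13080	13299
2018	303	15600	15903
2019	438	18397	18835
2020	463	17482	17945
2021	538	18552	19090
2022	493	21236	21729
2023	591	20589	21180
2024	739	23251	23990
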