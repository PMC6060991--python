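library_id	category	count	percent
CWRT-V1	total_reads	7046714	100.00
CWRT-V1	total_basepairs	345288986	100.00
CWRT-V1	total_mapped	5859055	83.15
CWRT-V1	perfect_match	4636536	65.80
CWRT-V1	mismatch_le3	1222519	17.35
CWRT-V1	unique_match	5329222	75.63
CWRT-V1	multi_match	529833	7.52
CWRT-V1	unmapped	1187659	16.85
CWRT-V2	total_reads	7231932	100.00
CWRT-V2	total_basepairs	354364668	100.00
CWRT-V2	total_mapped	5973616	82.60
CWRT-V2	perfect_match	4706869	65.08
CWRT-V2	mismatch_le3	1266747	17.52
CWRT-V2	unique_match	5510755	76.20
CWRT-V2	multi_match	462861	6.40
CWRT-V2	unmapped	1258316	17.40
CWRT-F2	total_reads	7155368	100.00
CWRT-F2	total_basepairs	350613032	100.00
CWRT-F2	total_mapped	5790541	80.93
CWRT-F2	perfect_match	4539940	63.45
CWRT-F2	mismatch_le3	1250601	17.48
CWRT-F2	unique_match	5319917	74.35
CWRT-F2	multi_match	470624	6.58
CWRT-F2	unmapped	1364827	19.07
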