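family	chrom	start	end	cytoband	size_bp	cnv_type	identity	genes
family1	chr5	119380128	119382128	5q23.1	2000	del	de_novo	-
family1	chr9	6700000	6710000	9p24.1	10000	del	de_novo	-
family1	chr10	26998675	27002675	10p12.1	4000	del	de_novo	PDSS1
family1	chr14	20314000	20328000	14q11.2	14000	amp	inherited	-
family1	chr15	22422114	22492114	15q11.2	70000	amp	de_novo	LOC642131
family1	chr16	34467150	34515150	16p11.2	48000	amp	de_novo	-
family1	chr16	55841801	55855801	16q12.2	14000	amp	inherited	CES1
family2	chr5	17612657	17620657	5p15.1	8000	del	-	-
family2	chr5	46244657	46246657	5p11	2000	amp	-	-
family2	chr5	135114128	135120128	5q31.1	6000	del	-	-
family2	chr12	114521470	114529470	12q24.21	8000	amp	-	-
family2	chr14	106926000	106930000	14q32.33	4000	amp	-	-
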