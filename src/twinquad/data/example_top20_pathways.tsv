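family	rank	pathway	shared_with	p_value
family1	1	CREB signaling in neurons	2A,2U	0.0000041687
family1	2	Neuropathic pain signaling in dorsal horn neurons	2A,1U,2U	0.0000083176
family1	3	Axonal guidance signaling	2A,1U	0.0000630957
family1	4	Cellular effects of sildenafil (Viagra)	2A,1U	0.0001479108
family1	5	Role of NFAT in cardiac hypertrophy	-	0.0001513561
family1	6	Dopamine-DARPP32 feedback in cAMP signaling	2A	0.0002290868
family1	7	Synaptic long term depression	2A,1U,2U	0.0002398833
family1	8	Wnt/Ca+ pathway	-	0.0003630781
family1	9	Synaptic long term potentiation	2A,2U	0.0008511380
family1	10	PPARa/RXRa activation	2U	0.0011748976
family1	11	Gap junction signaling	-	0.0013803843
family1	12	Glutamate receptor signaling	2A	0.0014791084
family1	13	14-3-3-mediated signaling	-	0.0020417379
family1	14	Netrin signaling	2A,1U,2U	0.0022908677
family1	15	Leptin signaling in obesity	-	0.0024547089
family1	16	Nitric oxide signaling in the cardiovascular system	2A,1U	0.0024547089
family1	17	Hepatic cholestasis	2U	0.0026915348
family1	18	Uracil degradation II (reductive)	2U	0.0029512092
family1	19	Thymine degradation	2U	0.0029512092
family1	20	Melatonin signaling	1U	0.0033113112
family2	1	Sperm motility	1U	0.0000053703
family2	2	Glutamate receptor signaling	1A	0.0000389045
family2	3	Neuropathic pain signaling in dorsal horn neurons	1A,2U,1U	0.0000575440
family2	4	Cellular effects of sildenafil (Viagra)	1A,1U	0.0002238721
family2	5	Nitric oxide signaling in the cardiovascular system	1A,1U	0.0002884032
family2	6	Synaptic long term depression	1A,2U,1U	0.0003235937
family2	7	CREB signaling in neurons	1A,2U	0.0003630781
family2	8	Synaptic long term potentiation	1A,2U	0.0005888437
family2	9	Phospholipase C signaling	-	0.0008709636
family2	10	Netrin signaling	1A,2U,1U	0.0010964782
family2	11	G-Protein coupled receptor signaling	2U	0.0012589254
family2	12	a-adrenergic signaling	-	0.0016595869
family2	13	Protein kinase A signaling	2U,1U	0.0023442288
family2	14	nNOS signaling in neurons	-	0.0040738028
family2	15	Huntington's disease signaling	-	0.0042657952
family2	16	Dopamine-DARPP32 feedback in cAMP signaling	1A	0.0058884366
family2	17	Cardiac b-adrenergic signaling	2U	0.0067608298
family2	18	Calcium signaling	2U	0.0077624712
family2	19	Breast cancer regulation by Stathmin 1	-	0.0087096359
family2	20	Axonal guidance signaling	1A,1U	0.0089125094
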