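variant_class	family	role	total	shared	unshared	shared_inherited	shared_de_novo	unshared_inherited	unshared_de_novo
ssc	family1	affected	4295920	-	11577	-	-	7302	4275
ssc	family1	unaffected	4265089	-	9345	-	-	5776	3569
ssc	family2	affected	3780127	-	10725	-	-	-	-
ssc	family2	unaffected	3789298	-	10351	-	-	-	-
cnv	family1	affected	152	145	7	131	14	2	5
cnv	family1	unaffected	154	145	9	131	14	5	4
cnv	family2	affected	156	151	5	-	-	-	-
cnv	family2	unaffected	157	151	6	-	-	-	-
sv	family1	affected	919	781	138	750	31	97	41
sv	family1	unaffected	893	781	112	750	31	66	46
sv	family2	affected	996	855	141	-	-	-	-
sv	family2	unaffected	977	855	122	-	-	-	-
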