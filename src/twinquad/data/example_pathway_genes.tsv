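pathway	family	gene
Dopamine-DARPP32 feedback in cAMP signaling	family1	PRKG2
Dopamine-DARPP32 feedback in cAMP signaling	family1	PPP2R1U
Dopamine-DARPP32 feedback in cAMP signaling	family1	GUCY1A3
Dopamine-DARPP32 feedback in cAMP signaling	family1	PRKAG2
Dopamine-DARPP32 feedback in cAMP signaling	family1	ADCY3
Dopamine-DARPP32 feedback in cAMP signaling	family1	PRKCB
Dopamine-DARPP32 feedback in cAMP signaling	family1	PRKAR1B
Dopamine-DARPP32 feedback in cAMP signaling	family1	KCNJ12
Dopamine-DARPP32 feedback in cAMP signaling	family1	ADCY2
Dopamine-DARPP32 feedback in cAMP signaling	family1	PRKCZ
Dopamine-DARPP32 feedback in cAMP signaling	family1	ADCY8
Dopamine-DARPP32 feedback in cAMP signaling	family1	PLCL1
Dopamine-DARPP32 feedback in cAMP signaling	family1	CACNA1D
Dopamine-DARPP32 feedback in cAMP signaling	family1	DRD3
Dopamine-DARPP32 feedback in cAMP signaling	family1	PLCB1
Dopamine-DARPP32 feedback in cAMP signaling	family1	GUCY1A2
Dopamine-DARPP32 feedback in cAMP signaling	family1	EP300
Dopamine-DARPP32 feedback in cAMP signaling	family1	PRKG1
Dopamine-DARPP32 feedback in cAMP signaling	family1	PPP3CA
Dopamine-DARPP32 feedback in cAMP signaling	family1	CACNA1A
Dopamine-DARPP32 feedback in cAMP signaling	family1	GRIN2U
Dopamine-DARPP32 feedback in cAMP signaling	family1	PLCG2
Dopamine-DARPP32 feedback in cAMP signaling	family1	KCNJ3
Dopamine-DARPP32 feedback in cAMP signaling	family1	PRKCA
Dopamine-DARPP32 feedback in cAMP signaling	family1	PLCH2
Dopamine-DARPP32 feedback in cAMP signaling	family1	CACNA1C
Dopamine-DARPP32 feedback in cAMP signaling	family1	PLCL2
Dopamine-DARPP32 feedback in cAMP signaling	family1	PLCZ1
Dopamine-DARPP32 feedback in cAMP signaling	family1	KCNJ10
Dopamine-DARPP32 feedback in cAMP signaling	family2	PLCB1
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKG2
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKG1
Dopamine-DARPP32 feedback in cAMP signaling	family2	PPM1L
Dopamine-DARPP32 feedback in cAMP signaling	family2	CAMK4
Dopamine-DARPP32 feedback in cAMP signaling	family2	PLCE1
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKAG2
Dopamine-DARPP32 feedback in cAMP signaling	family2	PPP2R2C
Dopamine-DARPP32 feedback in cAMP signaling	family2	ADCY10
Dopamine-DARPP32 feedback in cAMP signaling	family2	PPP1R14C
Dopamine-DARPP32 feedback in cAMP signaling	family2	GRIN2A
Dopamine-DARPP32 feedback in cAMP signaling	family2	CREB5
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKCA
Dopamine-DARPP32 feedback in cAMP signaling	family2	CACNA1C
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKCB
Dopamine-DARPP32 feedback in cAMP signaling	family2	KCNJ12
Dopamine-DARPP32 feedback in cAMP signaling	family2	ITPR1
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKAR1B
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKCI
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKCZ
Dopamine-DARPP32 feedback in cAMP signaling	family2	ADCY8
Dopamine-DARPP32 feedback in cAMP signaling	family2	PRKCG
Dopamine-DARPP32 feedback in cAMP signaling	family2	DRD3
Glutamate receptor signaling	family1	GRIA1
Glutamate receptor signaling	family1	GRIK2
Glutamate receptor signaling	family1	GRID1
Glutamate receptor signaling	family1	GNB1
Glutamate receptor signaling	family1	GRIN2U
Glutamate receptor signaling	family1	SLC1A7
Glutamate receptor signaling	family1	GRIK1
Glutamate receptor signaling	family1	GRIK4
Glutamate receptor signaling	family1	GRM7
Glutamate receptor signaling	family1	GRM1
Glutamate receptor signaling	family1	GRM5
Glutamate receptor signaling	family1	GRM8
Glutamate receptor signaling	family1	GRIK3
Glutamate receptor signaling	family2	GRID1
Glutamate receptor signaling	family2	GNG7
Glutamate receptor signaling	family2	CAMK4
Glutamate receptor signaling	family2	SLC1A2
Glutamate receptor signaling	family2	HOMER1
Glutamate receptor signaling	family2	SLC1A7
Glutamate receptor signaling	family2	GRIK1
Glutamate receptor signaling	family2	GRIN2A
Glutamate receptor signaling	family2	GRM4
Glutamate receptor signaling	family2	GRIK4
Glutamate receptor signaling	family2	SLC1A1
Glutamate receptor signaling	family2	GRM7
Glutamate receptor signaling	family2	GNG2
Glutamate receptor signaling	family2	GRM5
Glutamate receptor signaling	family2	GRM6
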