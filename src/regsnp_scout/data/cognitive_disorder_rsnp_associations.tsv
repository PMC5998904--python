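display_id	gene_id	index_rsid	trait
chr10:70716212	DDX21	rs2017305	Depression (quantitative trait)
rs200167248	PSMA5	rs12049330	Major depressive disorder
chr11:125462855	STT3A	rs548181	Combined
chr11:125462855	STT3A	rs548181	Schizophrenia
rs79148226	STT3A	rs548181	Schizophrenia
rs79148226	STT3A	rs548181	Combined
chr1:115054172	CSDE1	rs3827735	Autism
chr1:115054172	CSDE1	rs11102807	Autism
chr1:115259341	CSDE1	rs10489525	Autism
chr1:115259341	NRAS	rs10489525	Autism
chr1:115259341	CSDE1	rs8453	Autism
chr1:115259341	NRAS	rs8453	Autism
rs4951261	NUCKS1	rs823114	Parkinson's disease
rs823114	NUCKS1	rs823114	Parkinson's disease
rs7536483	NUCKS1	rs823128	Parkinson's disease
rs2303222	SETD1A	rs11865038	Parkinson's disease
rs2303222	AC135050.2	rs11865038	Parkinson's disease
rs2303222	STX4	rs11865038	Parkinson's disease
chr19:45394278	TOMM40	rs115881343	Cognitive decline (age-related)
chr19:45394278	TOMM40	rs2075650	Cognitive decline
chr19:45394955	TOMM40	rs115881343	Cognitive decline (age-related)
chr19:45394955	TOMM40	rs2075650	Cognitive decline
rs6116042	CDC25B	rs3761218	Bipolar disorder
chr3:183874023	EIF2B5	rs1969253	Major depressive disorder
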