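host_class	n_genomes	clade	total_loci
Agnatha	3	I	32
Agnatha	3	II	1
Agnatha	3	III	300
Chondrichthyes	6	I	2018
Chondrichthyes	6	II	0
Chondrichthyes	6	III	2843
Actinopterygii	173	I	8514
Actinopterygii	173	II	64
Actinopterygii	173	III	2177
Actinistia	1	I	0
Actinistia	1	II	0
Actinistia	1	III	97
Amphibia	34	I	17319
Amphibia	34	II	973
Amphibia	34	III	8019
Reptilia	92	I	13676
Reptilia	92	II	12120
Reptilia	92	III	20197
Aves	143	I	17951
Aves	143	II	20797
Aves	143	III	42014
Mammalia	452	I	215304
Mammalia	452	II	174549
Mammalia	452	III	143364
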