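virus_family	host_class	n_loci
Bornaviridae	Mammalia	2434
Bornaviridae	Aves	30
Bornaviridae	Reptilia	27
Bornaviridae	Amphibia	52
Bornaviridae	Actinopterygii	22
Bornaviridae	Agnatha	1
Chuviridae	Mammalia	24
Chuviridae	Reptilia	23
Chuviridae	Amphibia	9
Chuviridae	Actinopterygii	119
Chuviridae	Agnatha	7
Filoviridae	Mammalia	389
Filoviridae	Amphibia	1
Paramyxoviridae	Amphibia	4
Paramyxoviridae	Actinopterygii	14
Paramyxoviridae	Chondrichthyes	1
Flaviviridae	Mammalia	1
Flaviviridae	Actinopterygii	7
Hepadnaviridae	Aves	897
Hepadnaviridae	Reptilia	93
Hepadnaviridae	Amphibia	2
Hepadnaviridae	Chondrichthyes	1
Circoviridae	Mammalia	918
Circoviridae	Aves	32
Circoviridae	Reptilia	91
Circoviridae	Amphibia	82
Circoviridae	Actinopterygii	68
Circoviridae	Agnatha	7
Parvoviridae	Mammalia	534
Parvoviridae	Aves	34
Parvoviridae	Reptilia	34
Parvoviridae	Amphibia	12
Parvoviridae	Actinopterygii	12
Parvoviridae	Chondrichthyes	3
Herpesviridae	Mammalia	11
Herpesviridae	Aves	1
Herpesviridae	Reptilia	1
Alloherpesviridae	Amphibia	15
Alloherpesviridae	Actinopterygii	13
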