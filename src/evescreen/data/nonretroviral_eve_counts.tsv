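virus_family	genome_type	total_loci	total_events
Bornaviridae	ssRNA-ve	2566	383
Chuviridae	ssRNA-ve	182	164
Filoviridae	ssRNA-ve	390	69
Paramyxoviridae	ssRNA-ve	19	17
Flaviviridae	ssRNA+ve	8	11
Hepadnaviridae	DNArt	993	108
Circoviridae	DNAss	1198	131
Parvoviridae	DNAss	689	238
Herpesviridae	DNAds	13	8
Alloherpesviridae	DNAds	28	8
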