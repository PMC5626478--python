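# HEK293 anticodon-level tRNA read counts (tRNA-HydroSeq, mapped mature reads)
# anticodons are genomic-DNA 5'->3' (position 34 first); codons use slash
# shorthand for third-position alternatives
anticodon	amino_acid	read_count	codons
TGT	T	6484	ACA/G/C
AGG	P	6619	CCU/C
CGT	T	7664	ACG
CGG	P	9928	CCG
TAT	I	11902	AUA
TTG	Q	12533	CAA
TGG	P	12777	CCA/G/U
AAT	I	15657	AUU/C
AGT	T	16261	ACU/C
GCT	S	19618	AGC/U
GAA	F	20453	UUU/C
TAA	L	23330	UUA
TAG	L	23813	CUA
CCT	R	24943	AGG
CCC	G	25067	GGG
TAC	V	25169	GUA
CGA	S	25390	UCG
GTG	H	25607	CAU/C
CGC	A	25778	GCG
AAG	L	26991	CUU/C
CCA	W	30456	UGG
CAA	L	31930	UUG
CTG	Q	33162	CAG
GCA	C	34487	UGU/C
CCG	R	35475	CGG
TCC	G	36754	GGA
TCG	R	40154	CGA
TGA	S	40530	UCA
AGA	S	41241	UCU/C
TCT	R	52949	AGA
TTC	E	55795	GAA
GTC	D	57771	GAU/C
CAG	L	61112	CUG
ACG	R	66635	CGU/C
AGC	A	74964	GCU/C
GCC	G	77978	GGU/C
AAC	V	85733	GUU/C
TGC	A	92573	GCA
CAT	M	102919	AUG
CTC	E	113500	GAG
CAC	V	140741	GUG
TTT	K	161366	AAA
GTA	Y	181682	UAU/C
GTT	N	239876	AAU/C
CTT	K	340378	AAG
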