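patient_id	region_id	gene	chrom	pos	ref	alt	depth	alt_reads	consequence	in_dbsnp	is_indel
F01	R1	VHL	3	10183400	C	T	100	4	missense	False	False
F01	R1	VHL	3	10183500	G	A	20	1	missense	False	False
F01	R1	PBRM1	3	52580000	A	G	9	5	missense	False	False
F01	R1	PBRM1	3	52580100	T	C	200	100	synonymous	False	False
F01	R2	SETD2	3	47058000	C	A	100	50	missense	True	False
F01	R2	SETD2	3	47058100	C	CT	100	50	frameshift_indel	True	True
F01	R2	BAP1	3	52435100	G	T	950	300	missense	False	False
F01	R2	BAP1	3	52435200	C	T	400	40	nonsense	False	False
F01	R3	KDM5C	X	53220600	A	T	500	250	other	False	False
F01	R3	KDM5C	X	53220700	G	GTA	50	10	inframe_indel	False	True
F01	R3	VHL	3	10184000	T	G	1000	20	missense	False	False
F01	R3	VHL	3	10184100	A	C	100	6	synonymous	True	False
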