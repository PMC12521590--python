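accession	p1_position	protease	evidence
P10451	185	MMP3	reported
P10451	185	MMP7	reported
P98160	4195	BMP1	reported
P02768	174	MEP1B	reported
P02768	174	BACE2	reported
P02787	601	LGMN	reported
P02787	602	LGMN	reported
P10909	309	MMP3	reported
P10909	309	MMP12	reported
Q9BQT9	824	ADAMTS10	reported
Q9BQT9	824	ADAMTS17	reported
P02647	224	MMP7	reported
P02647	224	MMP12	reported
P02751	19	MMP2	reported
P02751	19	MMP8	reported
P02751	19	MMP13	reported
P02751	20	MMP2	reported
P02751	20	MMP8	reported
P02751	20	MMP13	reported
P0DJI8	22	CATL1	reported
P0DJI8	22	MMP3	reported
P0DJI8	22	CATB	reported
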