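system	variant_id	chrom	pos	ref	alt
ABO	ABO.261delG	chr9	136132908	TC	T
ABO	ABO.c526C>G	chr9	136131651	C	G
ABO	ABO.c703G>A	chr9	136131461	G	A
RH	RH.c307T>C	chr1	25420000	T	C
RH	RH.c676G>C	chr1	25408000	G	C
SYN01	SYN01.v1	chr1	10000	C	A
SYN01	SYN01.v2	chr1	10100	T	C
SYN01	SYN01.v3	chr1	10200	A	T
SYN01	SYN01.v4	chr1	10300	T	A
SYN01	SYN01.v5	chr1	10400	A	C
SYN02	SYN02.v1	chr2	10000	A	G
SYN02	SYN02.v2	chr2	10100	T	C
SYN02	SYN02.v3	chr2	10200	C	A
SYN02	SYN02.v4	chr2	10300	A	T
SYN02	SYN02.v5	chr2	10400	G	A
SYN02	SYN02.v6	chr2	10500	G	T
SYN03	SYN03.v1	chr3	10000	C	G
SYN03	SYN03.v2	chr3	10100	T	C
SYN03	SYN03.v3	chr3	10200	C	A
SYN03	SYN03.v4	chr3	10300	C	G
SYN03	SYN03.v5	chr3	10400	C	T
SYN03	SYN03.v6	chr3	10500	G	A
SYN04	SYN04.v1	chr4	10000	T	A
SYN04	SYN04.v2	chr4	10100	T	G
SYN04	SYN04.v3	chr4	10200	A	G
SYN04	SYN04.v4	chr4	10300	A	C
SYN04	SYN04.v5	chr4	10400	C	T
SYN05	SYN05.v1	chr5	10000	G	T
SYN05	SYN05.v2	chr5	10100	G	C
SYN05	SYN05.v3	chr5	10200	C	A
SYN05	SYN05.v4	chr5	10300	T	C
SYN05	SYN05.v5	chr5	10400	C	T
SYN05	SYN05.v6	chr5	10500	A	T
SYN05	SYN05.v7	chr5	10600	T	A
SYN06	SYN06.v1	chr6	10000	A	G
SYN06	SYN06.v2	chr6	10100	C	A
SYN06	SYN06.v3	chr6	10200	G	A
SYN06	SYN06.v4	chr6	10300	G	C
SYN06	SYN06.v5	chr6	10400	C	T
SYN07	SYN07.v1	chr7	10000	G	C
SYN07	SYN07.v2	chr7	10100	T	G
SYN07	SYN07.v3	chr7	10200	G	T
SYN07	SYN07.v4	chr7	10300	T	G
SYN07	SYN07.v5	chr7	10400	C	G
SYN07	SYN07.v6	chr7	10500	A	G
SYN07	SYN07.v7	chr7	10600	G	A
SYN08	SYN08.v1	chr8	10000	C	T
SYN08	SYN08.v2	chr8	10100	T	A
SYN08	SYN08.v3	chr8	10200	G	T
SYN08	SYN08.v4	chr8	10300	A	G
SYN08	SYN08.v5	chr8	10400	A	C
SYN08	SYN08.v6	chr8	10500	T	C
SYN08	SYN08.v7	chr8	10600	C	A
SYN08	SYN08.v8	chr8	10700	G	A
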