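system	allele_name	variant_ids	antigens
ABO	ABO*A1.01		A
ABO	ABO*B.01	ABO.c526C>G;ABO.c703G>A	B
ABO	ABO*O.01.01	ABO.261delG	
ABO	ABO*O.01.41	ABO.261delG;ABO.c526C>G;ABO.c703G>A	
RH	RH*ce		c;e
RH	RH*Ce	RH.c307T>C	C;e
RH	RH*cE	RH.c676G>C	E;c
RH	RH*CE	RH.c307T>C;RH.c676G>C	C;E
SYN01	SYN01*01		SYN01.AG1
SYN01	SYN01*02	SYN01.v1;SYN01.v2;SYN01.v3	SYN01.AG2
SYN01	SYN01*03	SYN01.v1;SYN01.v2;SYN01.v3;SYN01.v4;SYN01.v5	
SYN01	SYN01*04	SYN01.v1;SYN01.v2	SYN01.AG4
SYN01	SYN01*05	SYN01.v1;SYN01.v2;SYN01.v5	SYN01.AG5
SYN01	SYN01*06	SYN01.v1;SYN01.v2;SYN01.v4	SYN01.AG6
SYN01	SYN01*07	SYN01.v1;SYN01.v5	SYN01.AG7
SYN01	SYN01*08	SYN01.v1;SYN01.v3;SYN01.v4;SYN01.v5	SYN01.AG8
SYN02	SYN02*01		SYN02.AG1
SYN02	SYN02*02	SYN02.v1;SYN02.v3	SYN02.AG2
SYN02	SYN02*03	SYN02.v3;SYN02.v4;SYN02.v6	
SYN02	SYN02*04	SYN02.v2;SYN02.v5;SYN02.v6	SYN02.AG4
SYN02	SYN02*05	SYN02.v1;SYN02.v3;SYN02.v6	SYN02.AG5
SYN03	SYN03*01		SYN03.AG1
SYN03	SYN03*02	SYN03.v2;SYN03.v3;SYN03.v4;SYN03.v5;SYN03.v6	SYN03.AG2
SYN03	SYN03*03	SYN03.v1;SYN03.v2;SYN03.v5;SYN03.v6	
SYN03	SYN03*04	SYN03.v1;SYN03.v2;SYN03.v3;SYN03.v4;SYN03.v5;SYN03.v6	SYN03.AG4
SYN03	SYN03*05	SYN03.v1;SYN03.v2;SYN03.v4	SYN03.AG5
SYN03	SYN03*06	SYN03.v1;SYN03.v6	SYN03.AG6
SYN04	SYN04*01		SYN04.AG1
SYN04	SYN04*02	SYN04.v3;SYN04.v5	SYN04.AG2
SYN04	SYN04*03	SYN04.v2	
SYN04	SYN04*04	SYN04.v1	SYN04.AG4
SYN04	SYN04*05	SYN04.v3	SYN04.AG5
SYN04	SYN04*06	SYN04.v2;SYN04.v3;SYN04.v4;SYN04.v5	
SYN04	SYN04*07	SYN04.v2;SYN04.v3	SYN04.AG7
SYN05	SYN05*01		SYN05.AG1
SYN05	SYN05*02	SYN05.v2	SYN05.AG2
SYN05	SYN05*03	SYN05.v2;SYN05.v5;SYN05.v7	
SYN05	SYN05*04	SYN05.v4	SYN05.AG4
SYN05	SYN05*05	SYN05.v6	SYN05.AG5
SYN05	SYN05*06	SYN05.v1;SYN05.v2;SYN05.v3;SYN05.v5;SYN05.v6;SYN05.v7	
SYN06	SYN06*01		SYN06.AG1
SYN06	SYN06*02	SYN06.v1;SYN06.v2;SYN06.v3;SYN06.v4	SYN06.AG2
SYN06	SYN06*03	SYN06.v1;SYN06.v2;SYN06.v3;SYN06.v4;SYN06.v5	SYN06.AG3
SYN06	SYN06*04	SYN06.v1;SYN06.v2;SYN06.v4;SYN06.v5	SYN06.AG4
SYN06	SYN06*05	SYN06.v4	SYN06.AG5
SYN07	SYN07*01		SYN07.AG1
SYN07	SYN07*02	SYN07.v3;SYN07.v4;SYN07.v6	
SYN07	SYN07*03	SYN07.v6	SYN07.AG3
SYN07	SYN07*04	SYN07.v1;SYN07.v2;SYN07.v3;SYN07.v5;SYN07.v6;SYN07.v7	
SYN07	SYN07*05	SYN07.v1;SYN07.v2;SYN07.v4;SYN07.v5;SYN07.v6;SYN07.v7	SYN07.AG5
SYN08	SYN08*01		SYN08.AG1
SYN08	SYN08*02	SYN08.v1;SYN08.v2;SYN08.v4;SYN08.v7;SYN08.v8	SYN08.AG2
SYN08	SYN08*03	SYN08.v2;SYN08.v3;SYN08.v4;SYN08.v5;SYN08.v6;SYN08.v7;SYN08.v8	SYN08.AG3
SYN08	SYN08*04	SYN08.v1;SYN08.v2;SYN08.v4;SYN08.v5;SYN08.v6;SYN08.v7;SYN08.v8	SYN08.AG4
SYN08	SYN08*05	SYN08.v1;SYN08.v5;SYN08.v6	SYN08.AG5
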