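# genome_length: 15344
gene	type	start	end	strand	anticodon
cox1	PCG	1	1533	H	
trnL2	tRNA	1529	1592	H	TAA
cox2	PCG	1596	2280	H	
trnK	tRNA	2281	2351	H	TTT
trnG	tRNA	2355	2421	H	TCC
nad3	PCG	2422	2772	H	
trnA	tRNA	2796	2862	H	TGC
trnF	tRNA	2866	2929	L	GAA
nad5	PCG	2929	4641	L	
trnH	tRNA	4660	4725	L	GTG
nad4	PCG	4728	6068	L	
nad4l	PCG	6062	6343	L	
trnT	tRNA	6375	6443	H	TGT
nad6	PCG	6489	6980	H	
cob	PCG	6986	8122	H	
trnS2	tRNA	8121	8190	H	TGA
trnP	tRNA	8198	8264	L	TGG
nad1	PCG	8273	9202	L	
trnL1	tRNA	9233	9298	L	TAG
rrnL	rRNA	9276	10578	L	
trnV	tRNA	10612	10685	L	TAC
rrnS	rRNA	10687	11462	L	
CR	control_region	11463	11834	H	
trnM	tRNA	11834	11901	H	CAT
trnI	tRNA	11939	12002	H	GAT
nad2	PCG	12060	13055	H	
trnD	tRNA	13056	13122	H	GAT
atp8	PCG	13123	13281	H	
atp6	PCG	13275	13949	H	
cox3	PCG	13949	14740	H	
trnR	tRNA	14746	14809	H	TCG
trnN	tRNA	14810	14875	H	GTT
trnS1	tRNA	14876	14940	H	TCT
trnE	tRNA	14941	15010	H	TTC
trnW	tRNA	15014	15083	H	TCA
trnQ	tRNA	15099	15165	L	TTG
trnC	tRNA	15182	15245	L	GCT
trnY	tRNA	15258	15324	L	GTA
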