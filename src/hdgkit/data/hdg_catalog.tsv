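gene_symbol	ko_code	functional_group	cluster_id	subunit_role	general_metabolism	model_length_aa	provenance
alkB1_2	K00496	alkane		standalone	0	401	named
almA		alkane		standalone	0	480	named
ladA	K14338	alkane		standalone	0	440	named
rubB	K05297	alkane		standalone	1	380	named
bmoB	K16158	alkane	bmoBCDXYZ	structural	0	342	named
bmoC	K16159	alkane	bmoBCDXYZ	electron_transport_or_reductase	0	348	named
bmoD	K16160	alkane	bmoBCDXYZ	structural	0	120	named
bmoX	K16157	alkane	bmoBCDXYZ	structural	0	527	named
bmoY	K16161	alkane	bmoBCDXYZ	structural	0	389	named
bmoZ	K16162	alkane	bmoBCDXYZ	structural	0	289	named
prmA	K18223	alkane	prmABCD	structural	0	557	curated
prmB	K18224	alkane	prmABCD	structural	0	351	curated
prmC	K18225	alkane	prmABCD	structural	0	344	curated
prmD	K18226	alkane	prmABCD	electron_transport_or_reductase	0	338	curated
cyp153A	K15982	alkane		standalone	0	420	curated
alkH	K14519	alkane		standalone	0	490	curated
alkJ	K20898	alkane		standalone	0	550	curated
a-adh	K13953	MAH		standalone	1	370	named
ADH1	K13954	MAH		standalone	1	360	named
ped	K00114	MAH		standalone	1	590	named
phe	K16249	MAH		standalone	1	440	named
bsdC1	K18800	MAH	bsdC1D	structural	0	470	named
bsdD	K18801	MAH	bsdC1D	structural	0	82	named
bsdC2	K18802	MAH		standalone	0	466	named
cymAa	K10616	MAH	cymAab	structural	0	367	named
cymAb	K10617	MAH	cymAab	electron_transport_or_reductase	0	350	named
dmpK	K16243	MAH	dmpKLMNOP	structural	0	90	named
dmpL	K16244	MAH	dmpKLMNOP	structural	0	331	named
dmpM	K16245	MAH	dmpKLMNOP	structural	0	90	named
dmpN	K16246	MAH	dmpKLMNOP	structural	0	517	named
dmpO	K16247	MAH	dmpKLMNOP	structural	0	118	named
dmpP	K16248	MAH	dmpKLMNOP	electron_transport_or_reductase	0	353	named
etbAa	K18087	MAH	etbAabc	structural	0	455	named
etbAb	K18088	MAH	etbAabc	structural	0	190	named
etbAc	K18089	MAH	etbAabc	electron_transport_or_reductase	0	410	named
hcaB	K05711	MAH		standalone	1	270	named
hcaC	K05710	MAH	hcaCDEF	electron_transport_or_reductase	0	106	named
hcaD	K00529	MAH	hcaCDEF	electron_transport_or_reductase	0	400	named
hcaE	K05708	MAH	hcaCDEF	structural	0	453	named
hcaF	K05709	MAH	hcaCDEF	structural	0	158	named
todA	K18072	MAH	todABC1C2	electron_transport_or_reductase	0	410	named
todB	K18073	MAH	todABC1C2	electron_transport_or_reductase	0	107	named
todC1	K18074	MAH	todABC1C2	structural	0	450	named
todC2	K18075	MAH	todABC1C2	structural	0	187	named
xylA	K15757	MAH	xylAM	structural	0	491	named
xylM	K15758	MAH	xylAM	structural	0	365	named
xylB	K00141	MAH		standalone	0	486	curated
xylC	K00129	MAH		standalone	0	510	curated
catA	K03381	MAH		standalone	0	311	curated
tmoA	K15760	MAH	tmoABCDEF	structural	0	501	curated
tmoB	K15761	MAH	tmoABCDEF	structural	0	88	curated
tmoC	K15762	MAH	tmoABCDEF	electron_transport_or_reductase	0	112	curated
tmoD	K15763	MAH	tmoABCDEF	structural	0	103	curated
tmoE	K15764	MAH	tmoABCDEF	structural	0	327	curated
tmoF	K15765	MAH	tmoABCDEF	electron_transport_or_reductase	0	326	curated
nahB	K14585	PAH		standalone	1	259	named
phdK	K00152	PAH		standalone	1	497	named
gst	K00799	PAH		standalone	1	219	named
nahC	K14583	PAH		standalone	0	300	named
nidA	K14580	PAH	nidAB	structural	0	463	named
nidB	K14581	PAH	nidAB	structural	0	175	named
HPGDS	K04097	PAH		standalone	0	199	named
CYP2A6	K17683	PAH		standalone	0	494	named
CYP3A4	K17689	PAH		standalone	0	503	named
nahAc	K14579	PAH		standalone	0	449	curated
phnAc	K11943	PAH		standalone	0	439	curated
phdF	K18255	PAH		standalone	0	300	curated
phdE	K18257	various		standalone	1	271	named
adh	K00001	various		standalone	1	347	named
adhE	K04072	various		standalone	1	891	named
adhP	K18857	various		standalone	1	336	named
ALDH	K00128	various		standalone	1	501	named
frmA	K00121	various		standalone	1	369	named
sdh	K12960	various		standalone	1	588	named
chnB	K03379	various		standalone	0	542	named
yaiY	K18859	various		standalone	0	120	named
nmsA	K18860	various	nmsABC	structural	1	856	named
nmsB	K18861	various	nmsABC	structural	1	80	named
nmsC	K18862	various	nmsABC	structural	1	60	named
salDH	K00480	various		standalone	1	394	named
pcaG	K00448	various	pcaGH	structural	0	201	named
pcaH	K00449	various	pcaGH	structural	0	239	named
benA	K05549	various	benABC	structural	0	452	curated
benB	K05550	various	benABC	structural	0	161	curated
benC	K05784	various	benABC	electron_transport_or_reductase	0	349	curated
catB	K01856	various		standalone	0	373	curated
catC	K03464	various		standalone	0	97	curated
pobA	K00481	various		standalone	0	394	curated
boxA	K15511	various	boxAB	structural	0	708	curated
boxB	K15512	various	boxAB	structural	0	480	curated
ligA	K04100	various	ligAB	structural	0	140	curated
ligB	K04101	various	ligAB	structural	0	302	curated
xenA	K23256	various		standalone	0	364	curated
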