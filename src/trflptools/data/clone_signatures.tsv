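# Reference six-slot T-RF signatures of sequenced 16S clones from
# Fe(III)-reducing enrichments (forward = HEX/8F end, reverse = FAM/1492R end;
# NC = no recognition site, <50 = below the reliable sizing window).
phylotype_id	taxon	group	forward_MspI	forward_HhaI	forward_HaeIII	reverse_MspI	reverse_HhaI	reverse_HaeIII
AP-FeEnrich1	Geothrix	Geothrix	278	359	201	92	380	125
AP-FeEnrich2	Coriobacteriaceae	Actinobacteria	172	284	229	128	45	69
AP-FeEnrich3	Bacteroidetes	Bacteroidetes	90	94	NC	83	49	116
AP-FeEnrich4	Bacteroidetes	Bacteroidetes	424	86	<50	33	47	112
AP-FeEnrich5	Bacteroidetes	Bacteroidetes	201	86	<50	33	47	112
AP-FeEnrich6	Dysgonomonas	Bacteroidetes	95	100	<50	120	135	116
AP-FeEnrich7	Levilinea	Chloroflexi	159	536	220	76	390	125
AP-FeEnrich8	Clostridium	Firmicutes	179	193	271	124	403	43
AP-FeEnrich9	Acetobacterium	Firmicutes	216	371	NC	127	401	NC
AP-FeEnrich10	Duganella	Burkholderia	492	564	200	125	51	255
AP-FeEnrich11	Desulfobacca	Syntrophaceae	210	95	197	73	403	125
AP-FeEnrich12	Desulfobacter	Desulfobacter	515	95	209	127	405	125
AP-FeEnrich13	Desulfomicrobium	Desulfomicrobium	161	90.5	71.2	65	46	124
AP-FeEnrich14	Desulfovibrio putealis	Desulfovibrio	457	95	201	127	142	123
AP-FeEnrich15	Desulfovibrio	Desulfovibrio	507	93	201	68	143	122
AP-FeEnrich16	Desulfovibrio vulgaris	Desulfovibrio	289	57	75	74	270	35
AP-FeEnrich17	Geobacter	Geobacter	164	93	217	126	405	124
AP-FeEnrich18	Aeromonas salmonicida	Aeromonas	90	215	<50	123	221	124
AP-FeEnrich19	Aeromonas jandaei	Aeromonas	90	215	<50	123	221	124
AP-FeEnrich20	Shewanella	Shewanella	496	574	<50	127	49	123
AP-FeEnrich21	Serratia plymuthica	Enterobacteriaceae	493	373	206	127	49	123
AP-FeEnrich22	Serratia fonticola	Enterobacteriaceae	494	371	<50	127	49	123
AP-FeEnrich23	Klebsiella oxytoca	Enterobacteriaceae	494	371	<50	127	49	123
AP-FeEnrich24	Spirochaetes	Spirochaetes	210	62	210	126	146	125
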