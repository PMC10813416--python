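phylum	order	species	n_fl_types	n_intact_types	fl_length_bp	intact_length_bp	transposase_length_aa	tir_length_bp
Annelida	Crassiclitellata	Aporrectodea caliginosa	28	14	1416-5657	2223-5657	507-1316	8-61
Annelida	Crassiclitellata	Eisenia fetida	1	-	2167	-	-	-
Annelida	Crassiclitellata	Lumbricus rubellus	11	7	1705-4295	2318-4295	574-925	13-18
Annelida	Rhynchobdellida	Helobdella robusta	6	4	2190-2724	2313-2724	535-587	12-15
Annelida	Hirudinida	Hirudo medicinalis	1	-	1483-1518	-	-	-
Annelida	Terebellida	Paralvinella palmiformis	1	1	2587	2587	503	13
Arthropoda	Araneae	Argiope aurantia	16	3	1765-9505	2314-9505	544-577	13-18
Arthropoda	Araneae	Argiope trifasciata	21	8	1291-7726	2125-7726	500-640	12-18
Arthropoda	Araneae	Latrodectus hesperus	7	1	1773-3135	2168	558	6
Arthropoda	Araneae	Loxosceles reclusa	2	-	1314-2035	-	-	-
Arthropoda	Araneae	Parasteatoda tepidariorum	5	1	1680-2903	2133	564	7-16
Arthropoda	Araneae	Tetragnatha versicolor	7	2	1673-5404	3717-5404	584-687	9-14
Arthropoda	Balanomorpha	Amphibalanus amphitrite	5	3	1965-4732	2708-4732	506-645	13-18
Arthropoda	Decapoda	Callinectes sapidus	4	2	2177-4527	2763-3434	554-629	13-24
Arthropoda	Diplostraca	Daphnia obtusa	2	2	5295-6986	5295-6986	506-714	12-14
Arthropoda	Diplostraca	Daphnia pulex	1	-	2607-4619	-	-	-
Arthropoda	Diplostraca	Daphnia pulicaria	2	2	4407-8943	4407-8943	554-921	14-16
Arthropoda	Sarcoptiformes	Archegozetes longisetosus	2	2	2348-2362	2348-2359	523-567	7-11
Arthropoda	Siphonostomatoida	Lepeophtheirus salmonis	2	-	1698-1739	-	-	-
Chordata	Tetraodontiformes	Mola mola	1	-	2335-2350	-	-	-
Chordata	Tetraodontiformes	Pao palembangensis	2	1	1321-3029	3029	548	14
Chordata	Tetraodontiformes	Takifugu bimaculatus	4	2	1234-3869	3386-3869	549-562	14-35
Chordata	Tetraodontiformes	Takifugu flavidus	3	-	1966-3373	-	-	-
Chordata	Tetraodontiformes	Takifugu ocellatus	2	-	1384-2056	-	-	-
Chordata	Tetraodontiformes	Takifugu rubripes	3	1	1967-2750	2750	558	14
Echinodermata	Temnopleuroida	Lytechinus pictus	1	1	4650	4650	560	16
Echinodermata	Temnopleuroida	Lytechinus variegatus	2	2	4777-5974	4777-5974	559-614	5-16
Mollusca	Architaenioglossa	Biomphalaria glabrata	9	9	2226-3072	2226-3072	505-675	5-17
Mollusca	Chitonida	Acanthopleura granulata	2	2	2982-3061	2982-3061	522-703	15
Mollusca	Mytilida	Mytilisepta virgata	6	1	2433-5661	4089-4133	543	16
Mollusca	Ostreida	Crassostrea gigas	4	2	2348-6085	2348-2590	507-595	14-16
Mollusca	Ostreida	Crassostrea virginica	6	1	3850-6572	5268-5289	523-586	9
Mollusca	Ostreida	Ostrea edulis	4	3	2347-3184	2347-2678	507-638	12-14
Mollusca	Pectinida	Argopecten irradians irradians	4	1	3130-4412	4047-4053	590-626	15
Mollusca	Pectinida	Pinctada fucata	1	-	5595	-	-	-
Platyhelminthes	Tricladida	Girardia tigrina	21	1	1265-3478	2624-2627	504-525	13
Platyhelminthes	Tricladida	Schmidtea mediterranea	13	6	2126-3184	2359-3184	509-652	13-17
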