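#fosmid	cds_index	start	end	strand	gc_percent	function	feature_class	mobile_element	nj_lgt	ml_lgt	direction	top_hit_species	top_hit_accession	top_hit_evalue	top_hit_identity	top_hit_in_focal_group
7-14	1	18	920	+	53.0	Transposase for insertion sequence element ISRM5	protein_coding	1	no	no		Pseudoflavonifractor capillosus	ZP_02038860	2.00e-136	92	1
7-14	2	1459	1929	-	35.6	Teicoplanin resistance protein vanZ	protein_coding	0	novel	novel		Geobacillus thermodenitrificans	YP_001124564	7.00e-06	31	0
7-14	3	2346	3584	-	50.8	Putative transposase	protein_coding	1	lgt	lgt	from cluster_XIVa to cluster_IV	Coprococcus eutactus	ZP_02205788	2.00e-167	69	0
7-14	4	4214	5032	-	43.8	Hypothetical protein	protein_coding	0	novel	novel		Anaerostipes caccae	ZP_02418355	1.00e-03	39	0
7-14	5	6252	6962	-	51.9	Outer membrane lipoprotein-sorting protein	protein_coding	0	novel	novel		Caldicellulosiruptor saccharolyticus	YP_001179297	8.00e-06	31	0
7-14	6	6959	7480	-	47.3	RNA polymerase sigma-54 factor rpoN	protein_coding	0	unresolved	unresolved		Alkaliphilus oremlandii	YP_001512203	1.00e-28	40	0
7-14	7	7745	7820	none	63.2	tRNA-Pro (TGG)	tRNA	0	na	na						0
7-14	8	8265	10187	-	57.9	Large exoproteins involved in heme utilization or adhesion	protein_coding	0	unresolved	unresolved		Herpetosiphon aurantiacus	YP_001545021	2.00e-58	35	0
7-14	9	10188	10862	-	55.4	Hypothetical protein	protein_coding	0	unresolved	unresolved		Anaerotruncus colihominis	ZP_02440985	3.00e-38	56	1
7-14	10	10855	11580	-	54.4	Hypothetical protein	protein_coding	0	lgt	lgt	unresolved	Desulfitobacterium hafniense	YP_517449	7.00e-67	56	0
7-14	11	11732	12193	-	52.8	Iron-sulfur cluster regulator IscR	protein_coding	0	unresolved	no		Anaerotruncus colihominis	ZP_02443971	2.00e-44	65	1
7-14	12	12428	13360	+	59.1	Cysteine synthase	protein_coding	0	unresolved	unresolved		Faecalibacterium prausnitzii	ZP_02090920	4.00e-123	83	1
7-14	13	13706	13840	-	46.7	Sodium/glutamate symporter	protein_coding	0	unresolved	unresolved		Eubacterium siraeum	ZP_02423775	5.00e-12	80	1
7-14	14	13795	14877	-	56.7	Sodium/glutamate symporter	protein_coding	0	unresolved	unresolved		Eubacterium siraeum	ZP_02423775	7.00e-134	73	1
7-14	15	14895	15938	-	61.3	Immunogenic protein	protein_coding	0	unresolved	unresolved		Coprococcus eutactus	ZP_02205701	6.00e-61	44	0
7-14	16	16214	17023	-	57.9	8-oxoguanine-DNA-glycosylase	protein_coding	0	lgt	lgt	from cluster_XIVa to cluster_IV	Ruminococcus torques	ZP_01966859	9.00e-55	43	0
7-14	17	17025	18026	-	57.6	L-asparaginase	protein_coding	0	unresolved	unresolved		Clostridium bolteae	ZP_02087774	7.00e-103	54	0
7-14	18	18036	19133	-	62.6	Exonuclease SbcD	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02034908	3.00e-98	55	1
7-14	19	19130	19684	-	56.8	EBSC protein	protein_coding	0	unresolved	unresolved		Clostridium leptum	ZP_02078782	2.00e-54	68	1
7-14	20	19651	20424	-	55.9	Phosphoesterase family protein	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02034909	4.00e-87	61	1
7-14	21	21133	21414	-	50.7	Hypothetical protein	protein_coding	0	unresolved	unresolved		Eubacterium siraeum	ZP_02423392	2.00e-08	35	1
7-14	22	22289	23032	+	54.6	Transposase for insertion sequence element ISRM5	protein_coding	1	no	no		Pseudoflavonifractor capillosus	ZP_02038860	1.00e-110	87	1
7-14	23	23434	23508	none	58.7	tRNA-Glu (CTC)	tRNA	0	na	na						0
7-14	24	23684	23759	none	52.6	tRNA-Lys (CTT)	tRNA	0	na	na						0
7-14	25	23856	26709	none	52.5	23S rRNA gene	rRNA	0	na	na						0
7-14	26	27033	27109	none	63.6	tRNA-Ile (GAT)	tRNA	0	na	na						0
7-14	27	27121	27196	none	53.9	tRNA-Ala (TGC)	tRNA	0	na	na						0
7-14	28	27324	28847	none	53.5	16S rRNA gene	rRNA	0	na	na						0
7-14	29	29448	30365	-	57.4	Germination and sporulation	protein_coding	0	lgt	no	from cluster_XIVa to cluster_IV	Pseudoflavonifractor capillosus	ZP_02038021	1.00e-25	38	1
7-14	30	30362	31768	-	60.5	Osmosensitive K+ channel histidine kinase kdpD	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02038022	1.00e-120	52	1
7-14	31	31788	32465	-	55.8	Two-component response regulator SA14-24	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02036840	7.00e-86	76	1
7-14	32	32486	32854	-	55.3	Late competence protein comEA, DNA receptor	protein_coding	0	unresolved	unresolved		Cand. Desulforudis audaxviator	YP_001718193	3.00e-15	58	0
7-14	33	33191	34558	+	57.1	D-alanyl-D-alanine carboxypeptidase	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02036838	3.00e-07	47	1
7-14	34	34607	35155	-	59.7	Nitroreductase family protein	protein_coding	0	unresolved	lgt	from cluster_XIVa to cluster_IV	Clostridium kluyveri	YP_001393744	9.00e-36	50	0
7-25	1	1	794	+	51.5	Integrase	protein_coding	1	lgt	lgt	from cluster_XIVa to cluster_IV	Clostridium bolteae	ZP_02083674	6.00e-90	62	0
7-25	2	910	2469	-	57.8	GMP synthase [glutamine-hydrolyzing]	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02035344	0.00e+00	82	1
7-25	3	2447	2962	-	56.2	Xanthine phosphoribosyltransferase	protein_coding	0	unresolved	unresolved		Coprococcus eutactus	ZP_02207218	3.00e-43	54	0
7-25	4	3418	4239	-	60.5	Nucleotide-binding protein	protein_coding	0	no	no		Eubacterium siraeum	ZP_02421312	4.00e-91	64	1
7-25	5	4308	6572	-	61.3	Chromosome partition protein smc	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02034907	6.00e-103	35	1
7-25	6	7160	8682	none	53.6	16S rRNA gene	rRNA	0	na	na						0
7-25	7	8810	8885	none	55.3	tRNA-Ala (TGC)	tRNA	0	na	na						0
7-25	8	8897	8973	none	64.9	tRNA-Ile (GAT)	tRNA	0	na	na						0
7-25	9	9297	12150	none	52.5	23S rRNA gene	rRNA	0	na	na						0
7-25	10	12247	12322	none	53.9	tRNA-Lys (CTT)	tRNA	0	na	na						0
7-25	11	12498	12572	none	58.7	tRNA-Glu (CTC)	tRNA	0	na	na						0
7-25	12	12864	12939	none	57.9	tRNA-Asn (GTT)	tRNA	0	na	na						0
7-25	13	12994	13070	none	61.0	tRNA-Met (CAT)	tRNA	0	na	na						0
7-25	14	13108	13183	none	59.2	tRNA-Trp (CCA)	tRNA	0	na	na						0
7-25	15	13246	13322	none	62.3	tRNA-Asp (GTC)	tRNA	0	na	na						0
7-25	16	13328	13403	none	59.2	tRNA-Thr (GGT)	tRNA	0	na	na						0
7-25	17	13613	14674	+	54.3	Transposase for insertion sequence element ISRM5	protein_coding	1	no	no		Pseudoflavonifractor capillosus	ZP_02038860	4.00e-131	89	1
7-25	18	15027	15791	+	40.4	Unknown	protein_coding	0	unresolved	no		Bacteroides thetaiotaomicron	NP_810500	1.00e-117	78	0
7-25	19	15913	17193	+	55.2	Hypothetical protein	protein_coding	0	unresolved	unresolved		Eubacterium siraeum	ZP_02421339	4.00e-86	44	1
7-25	20	17144	18088	+	56.9	Hypothetical protein	protein_coding	0	unresolved	unresolved		Eubacterium ventriosum	ZP_02027484	5.00e-66	43	0
7-25	21	18370	19662	+	58.0	Putative stomatin/prohibitin-family membrane protease subunit	protein_coding	0	lgt	lgt	unresolved	Clostridium acetobutylicum	NP_349972	2.00e-92	48	0
7-25	22	19560	20867	+	57.0	Protein RtcB	protein_coding	0	no	no		Pseudoflavonifractor capillosus	ZP_02038919	2.00e-154	69	1
7-25	23	20864	21208	+	55.1	Predicted nucleotidyltransferase	protein_coding	0	unresolved	unresolved		Escherichia coli	ZP_03048733	5.00e-16	59	0
7-25	24	22686	23951	+	53.7	Hypothetical lipoprotein	protein_coding	0	lgt	lgt	from cluster_XIVa to cluster_IV	Clostridium bolteae	ZP_02087827	0.00e+00	82	0
7-25	25	24010	25620	+	48.6	ABC-type sugar transport system, ATP-binding protein	protein_coding	0	lgt	lgt	from cluster_XIVa to cluster_IV	Clostridium bolteae	ZP_02087828	0.00e+00	89	0
7-25	26	25634	26713	+	54.8	ABC transporter integral membrane protein	protein_coding	0	lgt	lgt	from cluster_XIVa to cluster_IV	Clostridium bolteae	ZP_02087829	2.00e-164	88	0
7-25	27	26710	27834	+	54.3	ABC transporter integral membrane protein	protein_coding	0	lgt	lgt	from cluster_XIVa to cluster_IV	Clostridium bolteae	ZP_02087830	7.00e-167	84	0
7-25	28	27831	28319	+	54.6	Hypothetical protein	protein_coding	0	lgt	lgt	unresolved	Clostridium bolteae	ZP_02087831	6.00e-47	70	0
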