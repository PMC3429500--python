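mirna_id	location	mfe	arm5	arm3	wt1	wt2	mt1	mt2
Novel01	scaffold_109:95168:95314	-41.2	TCTTGCTCAAATGAGTATTCCA	AGATACTCATTTGAGCTAGAAG	22	0	19	0
Novel02	scaffold_10:2672216:2672314	-53.01	CCATACCACAGCTGGATTCAGCC	CTGGATTCAGCTGTGGTATGGTA	0	14	7	0
Novel03	scaffold_10:4971000:4971152	-61.94	TAGCCAAGGATGACTTGCCT	GCAAGTCGTCTTTGGCTAGTC	0	0	74	0
Novel04	scaffold_15:2215354:2215608	-91.75	TAACGTTGACCAGTTGCACTAGT	ATGTGCAATAGGTCAATGTTAGG	0	0	6	0
Novel05	scaffold_19:1984361:1984493	-63.1	GGGCAATTCTCCTTTGGCAGA	CGCCAAAGGAGAATTGCCCTG	0	0	12	0
Novel06	scaffold_1:13086671:13086815	-57.94	TGAGGAAATTTCTGGAATGGG	CATTCCTTGGATTTCCTGCATT	0	0	23	0
Novel07	scaffold_22:3381361:3381439	-34.2	TCCTTGGGGTGATCTCGTAGT	GATGGGGTCGGTCCATGGATT	0	0	13	0
Novel08	scaffold_27:847685:847792	-72.1	GTGCCACAGTTGCATCCAGTC	CTGGATGTAATTGTGGCACGG	0	122	130	0
Novel09	scaffold_27:1650451:1650560	-73.1	GCCCCAATCCGTGGACAAAGG	TTTGTCCACGGATTGGGGCCA	0	0	65	0
Novel10	scaffold_2:3455812:3455930	-44.1	AGCTTGAGTCTTGCTGAAAGTA	CTTTCAGCAGCCTCCGGCGTC	0	51	46	0
Novel11	scaffold_2:6255278:6255381	-45	TTCTTTTTGCTACTTCTACTG	GTGGAAGTAGCAAAGAAAAGC	0	0	10	0
Novel12	scaffold_64:1246869:1246958	-35.6	TTTTGTTGCATGATGCTGATAA	ACCCGCATCATGCAACAAAAG	0	26	47	0
Novel13	scaffold_73:771564:771820	-80.02	GCAAGTCGTCTTTGGCTATTT	TAGCCAAGAATGACTTGCCCG	202	0	96	0
Novel14	scaffold_73:771772:771902	-54.6	TAGCCAAGGATGACTTGCCT	GCAAGTCGTCTTTGGCTATT	231	0	104	0
Novel15	scaffold_82:519444:519576	-70.3	TGCAACTGTGGTACGGTACCA	GTACCATACCACAGTTGCAAC	0	0	26	116
Novel16	scaffold_83:437489:437629	-56.7	TAGCCAAGGATGACTTGCCT	AGCAAGCATCCTGGGCTAAT	239	39	210	53
Novel17	scaffold_8:587742:587859	-65.9	GTTGAACGTAATATACACACA	TGTGTATGTTACGTTCAACGT	0	26	47	0
Novel18	scaffold_95:631652:631790	-57.4	TAGCCAAGGATGACTTGCCT	AGGCAGTCTCCTTGGCTAAG	122	8	71	0
Novel19	scaffold_95:743113:743226	-51.21	TAGCCAAGGATGACTTGCCT	GCAGTCTCCTTGGCTAACT	103	0	39	0
Novel20	scaffold_118:430222:430304	-21.6	ATGGAGTAAATCATGGCCGTCGG	GGACGCTCAGGATTGCGCCATGT	0	0	0	21
Novel21	scaffold_128:225135:225278	-89.7	TATGTTGCAACTGTGGTATGGTA	CCATACCACAGTTGCAACATAGC	328	184	470	210
Novel22	scaffold_129:473882:473988	-28.4	ATTGACTGATGAGGTGTCACAAT	TGTGGCAGCATATCAGTGGACGA	0	0	0	23
Novel23	scaffold_12:4547645:4547798	-92.1	TTCGGGATTTTAAAGTGCGGG	CGCACTTTAAAATCCCGGATT	0	162	0	151
Novel24	scaffold_14:4093405:4093478	-20.6	GTGGATTGGATGCGGATTTGA	ATATCCAACCCATCATTTTACAG	0	0	0	9
Novel25	scaffold_15:3899911:3900025	-55	TGCCTGGCTCCCTGTATGCCG	GCGTACGAGGAGCCAAGCATA	9456	14747	7725	10985
Novel26	scaffold_16:1864426:1864631	-140.2	TCATGCAATTGTAGTCAAAGT	TTTGACTACAATTGCATGACA	0	14	0	10
Novel27	scaffold_18:88175:88313	-49.3	GGGACTGTTGTCTGGTTCAAGG	TCGGACCAGGCTTCATTCCCCT	0	0	0	163
Novel28	scaffold_1:4611433:4611594	-59.94	TCGCTTGGTGCAGGTCGGGAA	CCCGCCTTGCATCAACTGAAT	34741	58284	18691	38895
Novel29	scaffold_27:1236405:1236538	-46.7	TTGGACAGAGAAATCACGGTCA	ACCGTGTTTCTCTGCCCAATC	427138	300236	399942	423804
Novel30	scaffold_2:4942371:4942595	-100.8	AAGCCAAAATGACACCCTTTCCT	GAAAGAGTGTCGTTTTTGGCTTGG	0	0	0	6
Novel31	scaffold_30:2196438:2196578	-34.6	AGAGAAGTAAGATATTTCCTTGG	AAGGATGTATCTTTTGTCTTTGA	0	0	0	7
Novel32	scaffold_39:1391080:1391195	-57	CGCACCCCAGCGTGGAACCATC	TGGTGCCACGCTGTGTGCGTC	122	8	86	53
Novel33	scaffold_39:1799757:1799942	-70.5	CAGCCAAGGATGACTTGCCGG	CGGCAAGTTGTCTTTGGCTAC	757	185	712	164
Novel34	scaffold_3:6400070:6400194	-46.14	TGAAGCTGCCAGCATGATCTA	GGTCATGCTCTGACAGCCTCACT	0	5811	3490	9998
Novel35	scaffold_49:246191:246294	-42	TGACAATGAGAGAGAGCACAC	GTGCTCTCTACCATTGTCATA	180	73	80	85
Novel36	scaffold_51:957676:957782	-76.2	TTGTGCTGAGCACCGGATCAA	GATCCGGTGCTCAGCACAAGC	0	16	0	37
Novel37	scaffold_52:447370:447483	-37.6	AACAAGCGTGTAGATCAGCTG	GCTGCGTTAAATACTTGTTGG	0	0	0	24
Novel38	scaffold_53:1195181:1195275	-52.9	TTGTCGCAGGAGCGGTGGCACC	TGCCAGCATCCTGTGACAAGA	159	0	0	422
Novel39	scaffold_57:106595:106727	-87.6	TGCAACTGTGGTACCGTGCTA	GCACGGTACCACAGTTGCACC	43	0	42	68
Novel40	scaffold_5:715526:715624	-41.1	TGTTGGCATAGCTCAATCCGA	TGATTGAGCCGTGCCAATATC	0	0	0	68
Novel41	scaffold_6:4465828:4465981	-59.5	TTCCAAAGGGATCGCATTGATC	TCATGCGATCCCTTCGGAATT	374	1411	260	1834
Novel42	scaffold_77:492511:492620	-23.52	TGGAAAATAATGATCGTAGAA	CTACGCTCTACTGTTTGCCACCAAT	3192	616	2477	7
Novel43	scaffold_81:895369:895480	-84	TCATACCACAGCTGCACCTAG	AGGTGCAGCTGTGGTATGGTA	0	0	0	31
Novel44	scaffold_8:1444329:1444467	-56.5	GCGGCATCATCAAGATTCACA	GAATCTTGATGATGCTGCAT	0	0	26	116
Novel45	scaffold_8:3530405:3530512	-47.7	GTAGCATCATCAAGATTCACA	AGAATCTTGATGATGCTGCAT	9464	27362	8865	32423
Novel46	scaffold_9:4701627:4701969	-107.6	GGAATGTTGTCTGGCTCAAGG	TTGGACCAGGCTTCATTCCAC	3593	0	0	1931
Novel47	scaffold_11:564547:564628	-38	TTTAAAATCACACGGCTTTAA	AAAACCATGCGGTTTTAAAGG	7	0	0	0
Novel48	scaffold_11:2291314:2291391	-18.7	CAATCGATGGATTGGATATGGA	CGTAAAAATCCGTGAATCTGTA	18	0	0	0
Novel49	scaffold_164:51980:52061	-22.2	ACCCAAATCACACAATCAAAGTTT	ATTTATTGTTGATATGGGTCA	30	0	0	0
Novel50	scaffold_20:1575648:1575778	-58.9	CCACAGGGGCGACCTGAGAAC	TCTCATGTCGCCCCTGCGGGA	6	0	0	0
Novel51	scaffold_3:4619018:4619126	-42.79	TGGAGAAGCAGGGCACGTGCAAA	TGCACGCGCTCCCCTTCTCCAAC	23	15	25	0
Novel52	scaffold_4:4045480:4045585	-40.6	TCCCACAGCTTTATTGAACCGC	AGTTCAAGAAAGCTGTGGAAAA	11	0	0	0
Novel53	scaffold_4:4081925:4082032	-38.9	CGATATTGGTGAGGTTCAATC	TTGAGCCGCGCCAATATCACT	53	0	0	0
Novel54	scaffold_4:4121669:4121798	-60.7	GTGACAGAAGAGAGTGAGCAC	GCTCACTCTCTATCTGTCACC	47	16	0	0
Novel55	scaffold_76:1019946:1020071	-23.67	ATAGTCTGAAGTAGAAGATAGTT	CTAGCATTTTGACTTCAGATCGTGTTA	10	0	0	0
Novel56	scaffold_80:25066:25172	-49.8	TTGACGGAAGATAGAGAGCAC	GCTCTCTATTCTTCTGTCATCA	3993830	1867066	4155155	2288840
Novel57	scaffold_95:696868:696981	-44.9	TAGCCAAGGATGACTTGCCT	GCAGTCTCCTTGGCTAAGC	150	8	86	0
Novel58	scaffold_95:743113:743226	-51.21	TAGCCAAGGATGACTTGCCTGA	AGGCAGTCTCCTTGGCTAACT	103	0	39	0
Novel59	scaffold_9:4621734:4621925	-59.1	TTGGACCAGGCTTCATTCCTC	GGAATGTTGTCTGGTTCAAGA	2404	0	0	0
Novel60	scaffold_103:171417:171509	-30.4	GCTTTCTCCCTCTAACTCGTCG	TCAAGTTAGAGAGAGAAAGCGT	0	14	7	0
Novel61	scaffold_12:3883367:3883573	-86.8	GAGCTTTCTTCGGTCCACTT	TTGGACTGAAGGGAGCTCCC	0	42	0	0
Novel62	scaffold_13:4483423:4483508	-22	CTACTTGGTAGGATACTTGGG	TGAGTATTTTCTACTGAGTGGCT	0	98	0	0
Novel63	scaffold_15:395989:396110	-25.9	TACAACTGTGGCAAGAAATGGCA	TCATCAAATGCTCAAGGGTGTGTAGC	0	17	0	0
Novel64	scaffold_17:2390469:2390560	-63.9	CACGCGGCCATCTCTCATTGAG	CAATGAGAGCTGGCCATGTGGG	0	29	0	0
Novel65	scaffold_26:118376:118514	-42.2	CGAGCAGATCCTGACACGCTT	GCATGCCTTAGAAATTTTTCGAT	0	15	0	0
Novel66	scaffold_37:247375:247555	-38.5	TCCTATGAGAGTTCGCGATTTTA	AAATTACGTTCTCGTTGGGTA	0	33	0	0
Novel67	scaffold_39:1309710:1309970	-39.04	AGCAGATGATGATACAAAAACA	TTGTTGTAAGCAGAGTTTGTGGA	0	8	0	0
Novel68	scaffold_3:1219690:1219806	-26.2	TGCTGTGATGATTTATGAATGAAT	ATATTCGTAATTCTGAGCAGT	0	26	0	0
Novel69	scaffold_40:130452:130527	-18	TAAAGAGGGTAAAATAGCTAACA	TTAGTTATTTCCGTCTACAAA	0	21	0	0
Novel70	scaffold_43:656273:656366	-33.24	TCAACTCGGCGATGCATTAATTA	CTTAATGCATCGCCAAGTTGAAT	0	13	0	0
Novel71	scaffold_44:542896:542995	-53.5	TGCCTGGCTCCCTGTATGCTT	GCGTGCGAGGAGCCATGCATG	0	11	0	0
Novel72	scaffold_46:1225861:1225959	-54.3	TCATACACAACCAATAAGAACC	TTCTTATTGATTGTGTATGGTA	0	8	0	0
Novel73	scaffold_56:198262:198499	-51.7	AATTCGATTGGTAGATGGGTA	CCTGATTTAATCAATGAGTTGG	0	15	0	0
Novel74	scaffold_5:7200012:7200132	-24.8	GGCAATTCAGAGGCTCAGAGTAT	ATTTCGATCGTCATTGCCAA	0	9	0	0
Novel75	scaffold_8:587750:587857	-65.1	TTGAACGTAATATACACACAC	GTGTGTATGTTACGTTCAACG	0	26	47	0
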