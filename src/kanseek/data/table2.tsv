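AGI	Gene Symbol	ORP-rank	Distance	Location	Enrichment replicate 1	Enrichment replicate 2	FDR replicate 1	FDR replicate 2	80 min	160 min
AT1G19840	SAUR-like	2341	6906	DOWN	5,1	2,8	6,76E-18	1,05E-12	yes	yes
AT1G75590	SAUR-like	3037	1915	UP	5,8	2,5	2,21E-17	1,86E-04	yes	yes
AT2G21210	SAUR-like	157	149	UP	8,3	3,4	4,47E-119	9,21E-58	yes	yes
AT2G33310	IAA13	1242		in CDS	7,4	4,1	1,00E-33	1,71E-27	yes	yes
AT2G34650	PID	2130	3923	UP	5,7	2,8	6,51E-23	1,53E-12	yes	yes
AT2G38120	AUX1	158	10052	UP	7,3	4,2	3,04E-94	1,24E-79	yes	yes
AT3G23030	IAA2	165	171	UP	9,0	4,4	4,11E-103	3,88E-67	yes	yes
AT3G28860	ATMDR1	3763	3456	UP	5,0	2,2	1,49E-11	1,45E-01	yes	yes
AT3G28860	ATMDR1	3075	8677	DOWN	4,4	2,0	3,47E-16	8,40E-05
AT4G03400	DFL2	2385	2241	DOWN	7,4	3,1	9,71E-24	9,10E-08	yes	yes
AT4G03400	DFL2	1583	2654	DOWN	5,6	2,6	2,76E-33	1,08E-16
AT4G27260	GH3.5, WES1	2996	1074	UP	4,0	2,2	6,37E-13	1,14E-07	yes	yes
AT4G27260	GH3.5, WES1	5906	971	DOWN	5,0	1,3	4,55E-09	1,63E+07
AT5G47370	HAT2	3245	86	UP	4,6	2,3	1,64E-12	1,76E-05	yes	yes
AT5G54510	GH3.6, DFL1	2785	2222	DOWN	4,8	1,9	1,29E-22	1,16E-04	yes	yes
AT5G59780	MYB59	1240	5918	UP	5,6	3,3	2,16E-32	7,10E-28	yes	yes
AT5G61420	MYB28	1759	769	UP	6,2	2,7	5,59E-32	2,11E-13	yes	yes
AT5G61420	MYB28	1753	2117	UP	4,4	2,7	4,69E-22	6,78E-21
AT5G63160	BT1	16	1273	UP	9,1	4,7	2,98E-185	8,71E-136	-	yes
AT5G67300	ATMYB44	2070	381	UP	4,5	2,4	1,11E-21	1,87E-14	yes	yes
AT5G67300	ATMYB44	53	2438	UP	11,3	5,4	9,41E-140	1,06E-92
AT1G70940	PIN3	5237	20	UP	6,4	3,2	2,54E-03	2,51E+02	yes	yes
AT2G01420	PIN4	1622	367	UP	6,3	2,8	3,70E-35	3,35E-15	yes	yes
AT2G01420	PIN4	1630	973	DOWN	5,5	3,0	1,65E-27	7,06E-20
AT2G26560	PLA2A	2249	1401	UP	6,1	3,1	1,59E-20	5,88E-12	yes	yes
AT5G60450	ARF4	294	2112	UP	6,7	4,0	6,92E-70	1,80E-64	yes	yes
AT2G33860	ARF3/ETT	4041	1151	UP	3,9	3,1	6,30E-01	2,50E-07	-	-
AT1G15690	AVP1	3612	2238	UP	8,1	3,4	4,21E-13	8,87E-02	yes	yes
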