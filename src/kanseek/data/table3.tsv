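AGI	Gene symbol	REV Distance	REV Location	FDR replicate 1	FDR replicate 2	Enrichment replicate 1	Enrichment replicate 2	KAN1 Distance	KAN1 Location	Distance REV/KAN1 binding
AT1G22570	Major facilitator protein	1129	DOWN	1,19E-112	3,31E-68	13,5	6,2	920	UP	4085
AT1G25560	TEM1	2926	UP	2,15E-64	2,70E-31	11,7	4,9	3024	UP	61
AT1G51940	LysM-domain protein	1525	UP	1,22E-10	3,24E+02	4,5	1,8	5999	UP	4504
AT1G61660	bHLH transcription factor		in CDS	2,26E-37	1,47E-22	6,8	3,4	1365	UP	3405
AT1G66140	ZFP4		in CDS	3,75E-31	4,10E-17	6,1	2,9		in CDS	26
AT1G66140	ZFP4			1,49E-01	1,35E+02	4,0	2,2		in CDS	434
AT1G67710	ARR11	1466	UP	2,20E-54	6,92E-40	6,3	3,4	1375	UP	113
AT1G68130	IDD14	3051	UP	1,08E-12	9,72E-11	3,8	2,2	3357	DOWN	8739
AT1G68520	B-BOX zinc finger protein	741	DOWN	4,34E-26	3,09E-09	3,8	2,3	248	UP	2757
AT1G68520	B-BOX zinc finger protein			5,97E-14	2,76E-06	5,9	2,8	829	UP	3408
AT1G71880	SUC1	5858	UP	2,80E-74	1,99E-51	8,1	4,1	5878	UP	41
AT1G72300	Leucine-rich receptor protein	3145	UP	4,42E-22	4,03E-12	8,3	4,1	691	UP	2424
AT1G72300	Leucine-rich receptor protein			6,72E-09	1,69E-09	4,0	2,4	1465	UP	1630
AT3G02140	TMAC2	893	UP	2,04E-69	5,94E-57	10,5	5,9	201	UP	653
AT3G02140	TMAC2			1,01E-48	5,34E-34	7,4	3,7	2737	UP	1863
AT3G02140	TMAC2			4,50E-08	5,09E-03	4,8	2,5	3049	UP	2231
AT3G12920	BRG3	1579	DOWN	1,73E-04	8,92E-01	4,3	2,3	1782	UP	5019
AT3G12920	BRG3			1,22E-181	7,71E-141	13,2	7,0	4565	UP	7652
AT3G12920	BRG3			6,75E-90	8,25E-62	11,6	5,8	983	DOWN	568
AT3G12920	BRG3			1,13E-63	9,51E-49	9,9	5,4	2338	DOWN	797
AT3G15570	NPH3 family protein	1009	UP	6,12E-93	1,02E-63	8,9	4,4	1036	UP	14
AT3G54400	Aspartyl protease protein	602	UP	4,51E+02	8,26E+04	4,6	2,4	120	UP	402
AT3G56050	Protein kinase family protein	208	UP	4,29E-87	5,13E-48	8,8	3,9	274	UP	42
AT3G61460	BRH1	2196	UP	1,85E-17	4,61E-12	5,9	3,2	314	UP	1826
AT4G18700	CIPK12	282	DOWN	3,22E+00	3,57E+03	7,5	3,9	26	UP	2468
AT4G18700	CIPK12			4,36E-101	1,53E-92	8,4	5,0	133	DOWN	146
AT4G22190	unknown protein	2827	UP	1,45E-38	9,85E-30	8,1	4,5	1709	UP	1166
AT4G26540	Leucine rich repeat receptor	2234	UP	3,06E-86	1,40E-45	8,5	3,7	2160	UP	129
AT4G26540	Leucine rich repeat receptor			8,31E-78	1,31E-53	7,1	3,6	896	DOWN	6893
AT4G27260	GH3.5, WES1	2494	DOWN	6,37E-13	1,14E-07	4,0	2,2	1074	UP	6295
AT4G27260	GH3.5, WES1			4,55E-09	1,63E+07	5,0	1,3	971	DOWN	1591
AT5G05690	CPD	4847	UP	1,81E-06	1,67E-02	5,1	2,7	5642	UP	894
AT5G47370	HAT2	1548	UP	1,64E-12	1,76E-05	4,6	2,3	86	UP	1403
AT5G51550	EXL3	2573	UP	2,22E-174	1,08E-139	14,1	7,7	687	UP	1892
AT5G51550	EXL3			9,95E-19	1,35E-11	4,0	2,1	2133	UP	480
AT5G52060	ATBAG1, BAG1	739	UP	1,28E-20	2,48E-03	5,4	2,1	8	UP	745
AT5G64570	XYL4	2389	UP	1,84E-39	5,08E-19	4,9	2,2		in CDS	5597
AT5G64570	XYL4			5,70E-50	5,28E-46	7,7	4,6	331	UP	2090
AT5G67190	DEAR2	2710	UP	1,46E-33	1,01E-22	4,9	2,6	276	UP	2557
AT5G67190	DEAR2			5,02E-178	3,45E-151	14,2	8,1	1541	UP	1248
AT5G67190	DEAR2			1,28E-61	2,35E-45	6,9	3,6	1319	UP	6884
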