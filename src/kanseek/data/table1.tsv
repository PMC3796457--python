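AGI	Gene Symbol	ORP-rank	Distance	Location	Enrichment replicate 1	Enrichment replicate 2	FDR replicate 1	FDR replicate 2	80 min	160 min
AT1G13245	RTFL17	4140	2414	DOWN	4,3	2,7	8,20E-04	3,93E-04	yes	yes
AT1G13260	RAV1	1215	519	DOWN	5,5	2,7	2,66E-39	2,20E-23	yes	yes
AT1G13260	RAV1	1003	9835	UP	7,8	3,4	6,93E-49	1,03E-23
AT1G13260	RAV1	882	6034	UP	5,1	2,8	1,54E-43	1,79E-33
AT1G27320	AHK3	5004	630	DOWN	4,3	2,1	8,20E-04	1,29E+02	yes	yes
AT1G56010	NAC1	7940	1500	UP	4,1	2,0	2,30E+04	1,80E+07	yes	yes
AT1G73590	PIN1	1344	1049	DOWN	6,9	3,6	3,37E-34	8,69E-23	-	yes
AT1G78240	TSD2	3471	2653	UP	5,0	2,5	2,67E-11	4,39E-04	yes	yes
AT1G78240	TSD2	6421	3459	UP	6,0	2,0	4,37E-03	1,80E+07
AT1G78240	TSD2	866	5964	UP	12,8	6,1	3,27E-49	1,04E-29
AT1G78240	TSD2	3094	7048	UP	6,7	2,6	1,98E-19	1,28E-02
AT2G23760	SAW2	1267	436	UP	7,2	3,8	9,78E-36	5,35E-25	-	yes
AT2G23760	SAW2	1145	2496	DOWN	6,0	3,2	7,38E-38	5,57E-27
AT2G31070	TCP10	344	76	UP	8,0	4,3	6,40E-73	1,79E-54	yes	yes
AT2G34710	PHB	231	937	UP	10,2	4,2	1,91E-106	2,01E-52	yes	yes
AT3G14370	WAG2	3554	1208	UP	7,9	3,5	1,08E-12	1,58E-02	yes	yes
AT5G60970	TCP5	1164	2282	DOWN	7,3	4,4	1,15E-32	4,35E-30	yes	yes
AT5G60970	TCP5	1019	3044	DOWN	7,8	4,9	2,90E-34	6,91E-34
AT5G43603	MIR166F	2366	658	UP	3,8	2,7	2,25E-12	6,47E-18	yes	yes
AT5G61480	PXY	2404		in CDS	5,7	2,6	5,67E-22	7,40E-09	-	yes
AT5G67440	NPY3	434	413	UP	6,4	3,5	2,32E-65	1,24E-49	yes	yes
AT5G67440	NPY3	1623	184	DOWN	5,5	2,5	1,19E-32	2,38E-16
AT4G37590	NPY5	979	1452	UP	9,9	5,0	2,37E-43	3,80E-29	yes	yes
AT3G02170	LNG2	3204	3955	UP	5,3	2,9	3,08E-11	6,67E-07	yes	yes
AT5G15580	LNG1	4944		in CDS	10,7	2,6	1,57E-12	3,27E+06	yes	yes
AT5G61960	AML1	2123	2369	UP	5,6	1,4	3,33E-34	4,59E-06	yes	yes
AT5G61960	AML1	2265		in CDS	6,8	3,1	5,15E-23	3,05E-10
AT4G32880	ATHB8	1402	561	UP	1,8	6,5	1,69E-30	3,33E-23	yes	yes
AT2G46685	MIR166A	4624	3218	UP	2,3	4,8	4,90E-07	1,49E+02	-	-
AT1G65620	AS2	1750		in CDS	2,4	5,1	1,50E-34	6,53E-12	-	-
AT1G65620	AS2	2506	424	DOWN	2,4	5,9	1,72E-23	2,74E-06	-	-
AT5G16560	KAN1	1996	173	UP	1,8	4,5	2,88E-21	5,12E-16	-	-
AT5G16560	KAN1	2689	707	UP	2,6	9,3	8,92E-23	1,02E-04	-	-
AT5G16560	KAN1	2930	5046	UP	2,9	7,8	8,53E-23	4,06E-03	-	-
AT1G32240	KAN2	468	4442	DOWN	8,8	5	4,95E-61	4,17E-50	-	-
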