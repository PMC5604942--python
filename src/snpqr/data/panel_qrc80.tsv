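# QRC-80 identity panel, genome build b37 (GRCh37), positions 1-based.
# 74 fingerprint SNPs (category=fingerprint): bi-allelic autosomal markers shared
# across eight genotyping arrays, MAF>0.25 in all five 1000GP continental
# populations, strand-unambiguous (never A/T or C/G), one per 10MB region.
# raf = reference-allele frequency in the 2,504 multi-ethnic 1000GP individuals.
#
# 6 auxiliary markers: 4 ABO blood-group SNVs (category=abo) and 2 chr1/Y
# paralogous sex markers (category=sex). Auxiliary annotations are not part of
# the fingerprint and are exempt from the spacing / strand-ambiguity rules.
#   rs8176719  exon-6 delG; ref=del (b37 reference carries the deletion = O1
#              allele), alt=ins; DTC files report D/I tokens. raf = global O1
#              allele frequency (approximate, for simulation only).
#   rs41302905 alt T tags the O2 allele; rs8176746 alt T tags the B allele;
#   rs56392308 alt (delC) tags the A2 subtype; allele assignments follow dbSNP
#              b37 plus-strand annotations and are PROVISIONAL (documented in
#              docs/methods.md).
#   rs12743401 / rs12734338 map to paralogous regions on chr 1 and Y;
#              heterozygosity indicates a Y chromosome (male). Their b37
#              coordinates are PROVISIONAL placeholders; lookup is rsid-first,
#              so coordinates are not load-bearing. raf=1.0 encodes "the chr1
#              paralog allele"; the simulator draws them conditionally on sex.
#
# index	chrom	pos	rsid	ref	alt	raf	category
1	1	7202190	rs970973	T	C	0.539	fingerprint
2	1	34071525	rs1874045	C	T	0.571	fingerprint
3	1	110998854	rs7514102	G	A	0.435	fingerprint
4	1	161479745	rs1801274	A	G	0.479	fingerprint
5	1	183542387	rs2274064	T	C	0.489	fingerprint
6	1	203194186	rs2297950	C	T	0.303	fingerprint
7	1	225534219	rs7527925	T	C	0.476	fingerprint
8	1	248039713	rs3811445	A	G	0.608	fingerprint
9	2	26804247	rs935172	T	C	0.547	fingerprint
10	2	101638888	rs3739014	A	G	0.607	fingerprint
11	2	113309473	rs1545133	C	T	0.523	fingerprint
12	2	138420996	rs10206850	A	G	0.543	fingerprint
13	2	191301368	rs9646748	A	G	0.485	fingerprint
14	2	207041053	rs3732083	T	C	0.458	fingerprint
15	2	237149941	rs6756597	C	T	0.479	fingerprint
16	3	14755572	rs6765537	A	G	0.391	fingerprint
17	3	52727257	rs2289247	G	A	0.429	fingerprint
18	3	100963154	rs571391	G	A	0.652	fingerprint
19	3	122259606	rs9851180	T	C	0.538	fingerprint
20	3	193209178	rs6788448	T	C	0.427	fingerprint
21	4	42639186	rs898500	A	G	0.481	fingerprint
22	4	79443850	rs931606	G	A	0.519	fingerprint
23	4	187120211	rs13146272	C	A	0.585	fingerprint
24	5	1065399	rs737154	C	T	0.525	fingerprint
25	5	52193287	rs1531545	C	T	0.554	fingerprint
26	5	73339114	rs285599	C	T	0.394	fingerprint
27	5	96503523	rs160632	C	T	0.586	fingerprint
28	5	150943085	rs2304054	G	A	0.465	fingerprint
29	5	169685163	rs315717	C	T	0.508	fingerprint
30	6	31610686	rs1052486	A	G	0.499	fingerprint
31	6	129807629	rs2229848	C	T	0.667	fingerprint
32	6	147680359	rs9390459	A	G	0.532	fingerprint
33	6	167360389	rs2236313	T	C	0.375	fingerprint
34	7	33282577	rs7793096	G	A	0.502	fingerprint
35	7	99757612	rs3823646	G	A	0.537	fingerprint
36	7	141672604	rs10246939	T	C	0.476	fingerprint
37	7	156762248	rs12919	G	A	0.515	fingerprint
38	8	1514009	rs2301963	C	A	0.477	fingerprint
39	8	30973957	rs1800392	G	T	0.446	fingerprint
40	8	121228679	rs4870723	A	C	0.512	fingerprint
41	8	143761931	rs2294008	C	T	0.306	fingerprint
42	9	4576680	rs301430	T	C	0.364	fingerprint
43	9	15784631	rs1539172	A	G	0.478	fingerprint
44	9	116136198	rs1043836	C	T	0.615	fingerprint
45	9	133927878	rs10901333	A	G	0.459	fingerprint
46	10	6001696	rs3136618	C	T	0.507	fingerprint
47	10	30316208	rs2185724	T	C	0.373	fingerprint
48	10	99498234	rs3818876	G	A	0.53	fingerprint
49	10	124610027	rs1891110	G	A	0.528	fingerprint
50	10	134748331	rs12781609	C	T	0.402	fingerprint
51	11	14246296	rs1025412	G	A	0.515	fingerprint
52	11	33065394	rs1064005	C	T	0.38	fingerprint
53	11	73785326	rs4453265	T	C	0.476	fingerprint
54	12	16397734	rs1852450	C	A	0.489	fingerprint
55	12	58162739	rs703842	A	G	0.385	fingerprint
56	12	125467158	rs11558556	C	T	0.361	fingerprint
57	13	33703656	rs495680	T	C	0.585	fingerprint
58	13	50141345	rs4942848	G	A	0.616	fingerprint
59	14	23299135	rs1135641	G	T	0.464	fingerprint
60	14	73138189	rs1060570	C	A	0.449	fingerprint
61	14	101350298	rs3825569	T	C	0.506	fingerprint
62	16	4751045	rs863980	C	T	0.533	fingerprint
63	16	29998200	rs4077410	A	G	0.491	fingerprint
64	16	56995236	rs1800775	C	A	0.459	fingerprint
65	17	14005439	rs2159132	G	A	0.522	fingerprint
66	17	33749546	rs2586514	A	G	0.602	fingerprint
67	17	57963537	rs1292053	A	G	0.446	fingerprint
68	17	71196809	rs1026128	A	G	0.523	fingerprint
69	18	60027241	rs1805034	C	T	0.537	fingerprint
70	19	4288332	rs888930	A	G	0.412	fingerprint
71	19	17394124	rs2363956	T	G	0.486	fingerprint
72	19	49658367	rs3745298	C	T	0.459	fingerprint
73	20	52786219	rs2296241	G	A	0.492	fingerprint
74	22	19951271	rs4680	G	A	0.462	fingerprint
75	9	136132908	rs8176719	del	ins	0.63	abo
76	9	136131322	rs41302905	C	T	0.99	abo
77	9	136131651	rs8176746	G	T	0.89	abo
78	9	136131029	rs56392308	ins	del	0.96	abo
79	1	235000001	rs12743401	C	T	1.0	sex
80	1	235100001	rs12734338	A	G	1.0	sex
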