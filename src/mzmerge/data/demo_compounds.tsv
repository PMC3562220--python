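id	name	monoisotopic_mass	kegg_id	hmdb_id
CPD001	Glycine	75.03203	C00037	HMDB0000123
CPD002	L-Alanine	89.04768	C00041	HMDB0000161
CPD003	L-Serine	105.04259	C00065	HMDB0000187
CPD004	L-Proline	115.06333	C00148	HMDB0000162
CPD005	L-Valine	117.07898	C00183	HMDB0000883
CPD006	L-Threonine	119.05824	C00188	HMDB0000167
CPD007	L-Leucine	131.09463	C00123	HMDB0000687
CPD008	L-Isoleucine	131.09463	C00407	HMDB0000172
CPD009	L-Asparagine	132.05349	C00152	HMDB0000168
CPD010	L-Aspartate	133.03751	C00049	HMDB0000191
CPD011	L-Glutamine	146.06914	C00064	HMDB0000641
CPD012	L-Glutamate	147.05316	C00025	HMDB0000148
CPD013	L-Methionine	149.05105	C00073	HMDB0000696
CPD014	L-Histidine	155.06948	C00135	HMDB0000177
CPD015	L-Phenylalanine	165.07898	C00079	HMDB0000159
CPD016	L-Arginine	174.11168	C00062	HMDB0000517
CPD017	L-Tyrosine	181.07389	C00082	HMDB0000158
CPD018	L-Tryptophan	204.08988	C00078	HMDB0000929
CPD019	L-Lysine	146.10553	C00047	HMDB0000182
CPD020	L-Cysteine	121.01975	C00097	HMDB0000574
CPD021	D-Glucose	180.06339	C00031	HMDB0000122
CPD022	D-Fructose	180.06339	C00095	HMDB0000660
CPD023	Sucrose	342.11621	C00089	HMDB0000258
CPD024	Lactose	342.11621	C00243	HMDB0000186
CPD025	D-Ribose	150.05282	C00121	HMDB0000283
CPD026	myo-Inositol	180.06339	C00137	HMDB0000211
CPD027	Citrate	192.02700	C00158	HMDB0000094
CPD028	Succinate	118.02661	C00042	HMDB0000254
CPD029	Fumarate	116.01096	C00122	HMDB0000134
CPD030	L-Malate	134.02152	C00149	HMDB0000156
CPD031	Pyruvate	88.01604	C00022	HMDB0000243
CPD032	L-Lactate	90.03169	C00186	HMDB0000190
CPD033	alpha-Ketoglutarate	146.02152	C00026	HMDB0000208
CPD034	Oxaloacetate	132.00587	C00036	HMDB0000223
CPD035	Creatinine	113.05891	C00791	HMDB0000562
CPD036	Creatine	131.06948	C00300	HMDB0000064
CPD037	Urea	60.03236	C00086	HMDB0000294
CPD038	Uric acid	168.02834	C00366	HMDB0000289
CPD039	Caffeine	194.08038	C07481	HMDB0001847
CPD040	Choline	103.09971	C00114	HMDB0000097
CPD041	Betaine	117.07898	C00719	HMDB0000043
CPD042	Carnitine	161.10519	C00318	HMDB0000062
CPD043	Taurine	125.01466	C00245	HMDB0000251
CPD044	Hypoxanthine	136.03851	C00262	HMDB0000157
CPD045	Xanthine	152.03343	C00385	HMDB0000292
CPD046	Adenine	135.05450	C00147	HMDB0000034
CPD047	Adenosine	267.09675	C00212	HMDB0000050
CPD048	Inosine	268.08077	C00294	HMDB0000195
CPD049	Uridine	244.06954	C00299	HMDB0000296
CPD050	Cholesterol	386.35487	C00187	HMDB0000067
CPD051	Palmitic acid	256.24023	C00249	HMDB0000220
CPD052	Stearic acid	284.27153	C01530	HMDB0000827
CPD053	Oleic acid	282.25588	C00712	HMDB0000207
CPD054	Glycerol	92.04734	C00116	HMDB0000131
CPD055	Nicotinamide	122.04801	C00153	HMDB0001406
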