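gene	log2fc	t	p	q	n_a	n_b	tested
Gene0001	0.26487212073052646	1.008577178833601	0.346761944916127	0.5725008253771691	5	4	True
Gene0002	-0.14648656027482687	-0.9713543214716289	0.36373148644077535	0.5725008253771691	5	4	True
Gene0003	-0.06283653627928842	-0.4568395151072181	0.6616250148540418	0.8019697149745961	5	4	True
Gene0004	0.2064527047485818	1.0492259148058836	0.3289429616567476	0.5725008253771691	5	4	True
Gene0005	0.21994904046506036	1.1511990710476936	0.2874500045179082	0.5725008253771691	5	4	True
Gene0006	1.6304072928754643	15.281240037747306	1.2380719341082448e-06	4.9522877364329786e-05	5	4	True
Gene0007	-0.21379489997629975	-0.8146832190940876	0.44208426425183434	0.5725008253771691	5	4	True
Gene0008	1.4054386123119542	5.429855199430024	0.0009767685364315587	0.0044805669993244705	5	4	True
Gene0009	0.13413353739233358	0.860407193200463	0.41805632683586996	0.5725008253771691	5	4	True
Gene0010	0.18762033877360906	0.811694384705835	0.443688139667306	0.5725008253771691	5	4	True
Gene0011	1.2114877360713763	7.7831255348792885	0.00010858800734109446	0.0010858800734109444	5	4	True
Gene0012	0.17801628823185922	0.9370822555413841	0.3799120590044074	0.5725008253771691	5	4	True
Gene0013	-1.1390983291109293	-7.279530152629091	0.0001656539131803017	0.0012773579714332752	5	4	True
Gene0014	0.15741948174447273	0.908741228844554	0.3936975000281517	0.5725008253771691	5	4	True
Gene0015	-1.2097301906293545	-10.510372693428556	1.5395098447957994e-05	0.0002052679793061066	5	4	True
Gene0016	0.020583262823407722	0.107336665552871	0.9175335263431003	0.9533787654957209	5	4	True
Gene0017	-0.06789868151889422	-0.29160008541413335	0.7790443003792044	0.865604778199116	5	4	True
Gene0018	0.5488706319360723	3.9904109734332027	0.005253686454655039	0.017512288182183464	5	4	True
Gene0019	-1.567756336686621	-7.112171514767185	0.00019160369571499127	0.0012773579714332752	5	4	True
Gene0020	0.24550589668650247	1.178896581586521	0.27695335424274364	0.5725008253771691	5	4	True
Gene0021	-1.033054329946701	-6.51450179691584	0.0006237490999974164	0.0035642805714138086	4	4	True
Gene0022	-0.06706028469569603	-0.3137390498002704	0.7628619078035586	0.865604778199116	5	4	True
Gene0023	-0.004778706492050588	-0.0214354267582807	0.9834965322661408	0.9834965322661408	5	4	True
Gene0024	0.1545433699052765	1.138476667053384	0.29238064454907103	0.5725008253771691	5	4	True
Gene0025	0.2059869386304385	0.9063943347699233	0.3948555374130471	0.5725008253771691	5	4	True
Gene0026	0.027181708889536083	0.10980650810493282	0.9156445464678145	0.9533787654957209	5	4	True
Gene0027	0.13690406839545588	0.8402279137576656	0.42854269944172446	0.5725008253771691	5	4	True
Gene0028	0.2028314794851056	0.6393330331900945	0.5507433262907717	0.6884291578634646	3	4	True
Gene0029	-1.2978276877887502	-13.096122768230432	3.52942511796944e-06	7.05885023593888e-05	5	4	True
Gene0030	0.2223368161729482	1.4469035348524182	0.19117631577242933	0.5098035087264782	5	4	True
Gene0031	0.21701426306346505	1.0480453534513094	0.3294500687159174	0.5725008253771691	5	4	True
Gene0032	0.2358887880714704	1.0460217682051607	0.33032073725009164	0.5725008253771691	5	4	True
Gene0033	-1.414243682885349	-5.4003293437657085	0.001008127574848006	0.0044805669993244705	5	4	True
Gene0034	0.292035767688823	2.376461053634302	0.04913712403130613	0.14039178294658894	5	4	True
Gene0035	0.3519792437344016	4.160897032456636	0.004237009370643549	0.015407306802340176	5	4	True
Gene0036	0.22476321875578265	4.211489348883901	0.003978384485719825	0.015407306802340176	5	4	True
Gene0037	-1.558900291905399	-4.024697174377735	0.015802795774123992	0.04862398699730459	4	2	True
Gene0038	-0.01793126161446068	-0.09164931409136642	0.9295442963583278	0.9533787654957209	5	4	True
Gene0039	-0.1123431669425301	-0.40037893868901175	0.7008151327425357	0.8244883914618067	5	4	True
Gene0040	0.22393096622411335	1.377960634808996	0.21065044842557523	0.526626121063938	5	4	True
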