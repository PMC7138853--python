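gene	plex1	plex2	plex3
GENE0001	-0.09631767486632113	-0.13221721250511406	-0.5549777454168072
GENE0002	-0.16271463542796058	0.2106646894935634	-0.451871422100786
GENE0003	0.4670073372785008	0.08457780140817524	-0.7209359638613028
GENE0004	-0.20368530423165662	0.03895600716506729	0.23260171695846005
GENE0005	0.07883119876751597	0.1069230632245373	0.4090253702992159
GENE0006	0.044271877673267436	0.30162834951210626	0.13712291889265854
GENE0007	0.40152375459235734	-0.018321513076306067	0.07763829090940227
GENE0008	-0.39851176934026805	0.03260181967280983	-0.06367839170752936
GENE0009	-0.28652462147954955	-0.2123867697614615	-0.2656534932698276
GENE0010	0.3478118202145157	-0.04916490969949806	0.3613949140832859
GENE0011	0.051771308532300955	-0.08484601413614261	0.017448156986605436
GENE0012	0.14905559657787562	-0.06791120686674426	0.22340314106013595
GENE0013	0.22783869082098696	0.014641320185618093	-0.27703184086618626
GENE0014	-0.41228632552094713	0.02704840758661461	-0.06114805504886646
GENE0015	-0.04060288507908163	0.3051122294392813	-0.15227806632658167
GENE0016	0.3901073512979815	0.25881153841712007	-0.007906580252405258
GENE0017	-0.26650122021126266	0.13753357821274578	0.4265156732897572
GENE0018	0.6245599951126586	0.5126103366366925	0.32988071615502185
GENE0019	-0.24833257712849285	0.49814136708072987	0.24978635472582117
GENE0020	0.43752019372177614	0.15266408491658115	-0.5215637331455005
GENE0021	-0.042112907093362455	0.6209773274600017	0.1999331678646158
GENE0022	-0.17036881851162836	-0.12048055666228621	-0.11464314795162714
GENE0023	-0.023163834858168603	0.03490742844828153	-0.17083773881459716
GENE0024	-0.5438714421467715	0.27137447951611293	0.1730409774611904
GENE0025	-0.24081782471390176	0.012561907764253682	0.16606181210030996
GENE0026	-0.1120550824619609	0.482353057848212	-0.17905171414478455
GENE0027	0.09679303852326043	-0.30303208552191735	0.12701453915991856
GENE0028	0.7603443549335439	0.18761331748061247	0.6658666073174785
GENE0029	0.4524081245114735	0.24564072141998414	-0.4543676038422181
GENE0030	0.1326327057851072	-0.04566817517862781	0.20911182348626747
GENE0031	0.051552032743666286	0.07716563271210233	-0.2783305615452368
GENE0032	0.007403879325603682	-0.15871582763450637	0.12446741706687905
GENE0033	-0.09139282310483414	-0.20223400708756248	0.25344568745411444
GENE0034	0.3940454988791332	-0.09836927394238343	0.3413186722611716
GENE0035	-0.07515019120926004	-0.13318471798191273	-0.3842251754692611
GENE0036	-0.2336892720108063	-0.08739539057660285	0.08788784113261237
GENE0037	0.016928397178200882	0.7473172997812214	0.5896934041325886
GENE0038	0.09107668190611794	0.05083868010372174	-0.5318795527763417
GENE0039	0.15355746220698194	-0.1082923259760933	-0.39722470449195085
GENE0040	0.05809542602815157	-0.7217737345969769	-0.3842094987229571
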