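plex_id	spectrum_id	qc_violation
plex1	plex1.000001	
plex1	plex1.000002	
plex1	plex1.000003	
plex1	plex1.000004	
plex1	plex1.000005	
plex1	plex1.000006	
plex1	plex1.000007	
plex1	plex1.000008	ms1_low
plex1	plex1.000009	
plex1	plex1.000010	
plex1	plex1.000011	
plex1	plex1.000012	
plex1	plex1.000013	ms2_low
plex1	plex1.000014	
plex1	plex1.000015	
plex1	plex1.000016	
plex1	plex1.000017	
plex1	plex1.000018	
plex1	plex1.000019	
plex1	plex1.000020	
plex1	plex1.000021	
plex1	plex1.000022	
plex1	plex1.000023	
plex1	plex1.000024	
plex1	plex1.000025	
plex1	plex1.000026	
plex1	plex1.000027	
plex1	plex1.000028	
plex1	plex1.000029	
plex1	plex1.000030	
plex1	plex1.000031	
plex1	plex1.000032	ms2_low
plex1	plex1.000033	
plex1	plex1.000034	
plex1	plex1.000035	
plex1	plex1.000036	
plex1	plex1.000037	
plex1	plex1.000038	
plex1	plex1.000039	
plex1	plex1.000040	
plex1	plex1.000041	
plex1	plex1.000042	
plex1	plex1.000043	contaminant
plex1	plex1.000044	
plex1	plex1.000045	
plex1	plex1.000046	
plex1	plex1.000047	
plex1	plex1.000048	
plex1	plex1.000049	ms2_low
plex1	plex1.000050	
plex1	plex1.000051	
plex1	plex1.000052	
plex1	plex1.000053	
plex1	plex1.000054	
plex1	plex1.000055	
plex1	plex1.000056	
plex1	plex1.000057	
plex1	plex1.000058	
plex1	plex1.000059	
plex1	plex1.000060	
plex1	plex1.000061	
plex1	plex1.000062	
plex1	plex1.000063	
plex1	plex1.000064	
plex1	plex1.000065	
plex1	plex1.000066	
plex1	plex1.000067	
plex1	plex1.000068	
plex1	plex1.000069	reference_missing
plex1	plex1.000070	
plex1	plex1.000071	
plex1	plex1.000072	
plex1	plex1.000073	
plex1	plex1.000074	
plex1	plex1.000075	
plex1	plex1.000076	
plex1	plex1.000077	
plex1	plex1.000078	
plex1	plex1.000079	contaminant
plex1	plex1.000080	
plex1	plex1.000081	
plex1	plex1.000082	
plex1	plex1.000083	
plex1	plex1.000084	
plex1	plex1.000085	
plex1	plex1.000086	
plex1	plex1.000087	
plex1	plex1.000088	
plex1	plex1.000089	
plex1	plex1.000090	
plex1	plex1.000091	
plex1	plex1.000092	
plex1	plex1.000093	
plex1	plex1.000094	
plex1	plex1.000095	
plex1	plex1.000096	
plex1	plex1.000097	
plex1	plex1.000098	
plex1	plex1.000099	
plex1	plex1.000100	
plex1	plex1.000101	reference_missing
plex1	plex1.000102	
plex1	plex1.000103	
plex1	plex1.000104	
plex1	plex1.000105	
plex1	plex1.000106	
plex1	plex1.000107	
plex1	plex1.000108	
plex1	plex1.000109	
plex1	plex1.000110	
plex1	plex1.000111	
plex1	plex1.000112	
plex1	plex1.000113	
plex1	plex1.000114	
plex1	plex1.000115	
plex1	plex1.000116	
plex1	plex1.000117	
plex1	plex1.000118	
plex1	plex1.000119	
plex1	plex1.000120	
plex1	plex1.000121	
plex1	plex1.000122	
plex2	plex2.000001	
plex2	plex2.000002	
plex2	plex2.000003	
plex2	plex2.000004	
plex2	plex2.000005	
plex2	plex2.000006	
plex2	plex2.000007	ms2_low
plex2	plex2.000008	
plex2	plex2.000009	
plex2	plex2.000010	
plex2	plex2.000011	
plex2	plex2.000012	
plex2	plex2.000013	
plex2	plex2.000014	
plex2	plex2.000015	
plex2	plex2.000016	
plex2	plex2.000017	
plex2	plex2.000018	
plex2	plex2.000019	
plex2	plex2.000020	
plex2	plex2.000021	
plex2	plex2.000022	
plex2	plex2.000023	
plex2	plex2.000024	
plex2	plex2.000025	
plex2	plex2.000026	reference_missing
plex2	plex2.000027	
plex2	plex2.000028	
plex2	plex2.000029	
plex2	plex2.000030	contaminant
plex2	plex2.000031	
plex2	plex2.000032	
plex2	plex2.000033	
plex2	plex2.000034	
plex2	plex2.000035	
plex2	plex2.000036	
plex2	plex2.000037	
plex2	plex2.000038	purity
plex2	plex2.000039	
plex2	plex2.000040	
plex2	plex2.000041	
plex2	plex2.000042	
plex2	plex2.000043	
plex2	plex2.000044	
plex2	plex2.000045	
plex2	plex2.000046	
plex2	plex2.000047	
plex2	plex2.000048	
plex2	plex2.000049	
plex2	plex2.000050	
plex2	plex2.000051	
plex2	plex2.000052	
plex2	plex2.000053	purity
plex2	plex2.000054	
plex2	plex2.000055	
plex2	plex2.000056	
plex2	plex2.000057	
plex2	plex2.000058	
plex2	plex2.000059	
plex2	plex2.000060	
plex2	plex2.000061	
plex2	plex2.000062	
plex2	plex2.000063	
plex2	plex2.000064	
plex2	plex2.000065	
plex2	plex2.000066	contaminant
plex2	plex2.000067	ms2_low
plex2	plex2.000068	
plex2	plex2.000069	
plex2	plex2.000070	
plex2	plex2.000071	
plex2	plex2.000072	
plex2	plex2.000073	purity
plex2	plex2.000074	
plex2	plex2.000075	
plex2	plex2.000076	
plex2	plex2.000077	
plex2	plex2.000078	
plex2	plex2.000079	
plex2	plex2.000080	
plex2	plex2.000081	
plex2	plex2.000082	
plex2	plex2.000083	
plex2	plex2.000084	
plex2	plex2.000085	
plex2	plex2.000086	
plex2	plex2.000087	
plex2	plex2.000088	
plex2	plex2.000089	
plex2	plex2.000090	
plex2	plex2.000091	
plex2	plex2.000092	
plex2	plex2.000093	
plex2	plex2.000094	
plex2	plex2.000095	
plex2	plex2.000096	
plex2	plex2.000097	
plex2	plex2.000098	
plex2	plex2.000099	
plex2	plex2.000100	
plex2	plex2.000101	
plex2	plex2.000102	
plex2	plex2.000103	
plex2	plex2.000104	
plex2	plex2.000105	
plex2	plex2.000106	
plex2	plex2.000107	
plex2	plex2.000108	
plex2	plex2.000109	
plex2	plex2.000110	
plex2	plex2.000111	
plex2	plex2.000112	
plex2	plex2.000113	
plex2	plex2.000114	
plex2	plex2.000115	
plex2	plex2.000116	
plex2	plex2.000117	
plex3	plex3.000001	
plex3	plex3.000002	
plex3	plex3.000003	
plex3	plex3.000004	
plex3	plex3.000005	
plex3	plex3.000006	
plex3	plex3.000007	
plex3	plex3.000008	reference_missing
plex3	plex3.000009	
plex3	plex3.000010	
plex3	plex3.000011	
plex3	plex3.000012	
plex3	plex3.000013	
plex3	plex3.000014	
plex3	plex3.000015	purity
plex3	plex3.000016	
plex3	plex3.000017	
plex3	plex3.000018	
plex3	plex3.000019	
plex3	plex3.000020	
plex3	plex3.000021	
plex3	plex3.000022	
plex3	plex3.000023	
plex3	plex3.000024	
plex3	plex3.000025	
plex3	plex3.000026	contaminant
plex3	plex3.000027	
plex3	plex3.000028	
plex3	plex3.000029	
plex3	plex3.000030	
plex3	plex3.000031	
plex3	plex3.000032	
plex3	plex3.000033	
plex3	plex3.000034	
plex3	plex3.000035	
plex3	plex3.000036	
plex3	plex3.000037	
plex3	plex3.000038	
plex3	plex3.000039	
plex3	plex3.000040	
plex3	plex3.000041	
plex3	plex3.000042	probability
plex3	plex3.000043	
plex3	plex3.000044	
plex3	plex3.000045	
plex3	plex3.000046	
plex3	plex3.000047	
plex3	plex3.000048	
plex3	plex3.000049	
plex3	plex3.000050	
plex3	plex3.000051	
plex3	plex3.000052	
plex3	plex3.000053	
plex3	plex3.000054	reference_missing
plex3	plex3.000055	
plex3	plex3.000056	
plex3	plex3.000057	
plex3	plex3.000058	
plex3	plex3.000059	
plex3	plex3.000060	
plex3	plex3.000061	
plex3	plex3.000062	
plex3	plex3.000063	
plex3	plex3.000064	
plex3	plex3.000065	
plex3	plex3.000066	
plex3	plex3.000067	
plex3	plex3.000068	ms2_low
plex3	plex3.000069	
plex3	plex3.000070	
plex3	plex3.000071	
plex3	plex3.000072	
plex3	plex3.000073	
plex3	plex3.000074	
plex3	plex3.000075	
plex3	plex3.000076	
plex3	plex3.000077	
plex3	plex3.000078	
plex3	plex3.000079	
plex3	plex3.000080	
plex3	plex3.000081	
plex3	plex3.000082	
plex3	plex3.000083	
plex3	plex3.000084	
plex3	plex3.000085	ms2_low
plex3	plex3.000086	
plex3	plex3.000087	
plex3	plex3.000088	
plex3	plex3.000089	
plex3	plex3.000090	
plex3	plex3.000091	
plex3	plex3.000092	
plex3	plex3.000093	
plex3	plex3.000094	
plex3	plex3.000095	
plex3	plex3.000096	
plex3	plex3.000097	
plex3	plex3.000098	contaminant
plex3	plex3.000099	
plex3	plex3.000100	
plex3	plex3.000101	
plex3	plex3.000102	
plex3	plex3.000103	
plex3	plex3.000104	
plex3	plex3.000105	
plex3	plex3.000106	
plex3	plex3.000107	
plex3	plex3.000108	
plex3	plex3.000109	
plex3	plex3.000110	
plex3	plex3.000111	
plex3	plex3.000112	
plex3	plex3.000113	
plex3	plex3.000114	
plex3	plex3.000115	
plex3	plex3.000116	
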