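TRUE_DOWN	na	GENE0013	GENE0015	GENE0019	GENE0021	GENE0029	GENE0033	GENE0037
RANDOM_001	na	GENE0005	GENE0006	GENE0015	GENE0030	GENE0034	GENE0038
RANDOM_002	na	GENE0002	GENE0003	GENE0005	GENE0010	GENE0014	GENE0017	GENE0024	GENE0036
RANDOM_003	na	GENE0004	GENE0005	GENE0007	GENE0011	GENE0017	GENE0024	GENE0033	GENE0034
RANDOM_004	na	GENE0002	GENE0011	GENE0013	GENE0015	GENE0021	GENE0025	GENE0029	GENE0037	GENE0039	GENE0040
RANDOM_005	na	GENE0001	GENE0002	GENE0003	GENE0004	GENE0007	GENE0008	GENE0013	GENE0017	GENE0032	GENE0033
RANDOM_006	na	GENE0008	GENE0016	GENE0025	GENE0026	GENE0027	GENE0029	GENE0033	GENE0037
RANDOM_007	na	GENE0005	GENE0009	GENE0019	GENE0023	GENE0024	GENE0032	GENE0038	GENE0039	GENE0040
RANDOM_008	na	GENE0003	GENE0008	GENE0009	GENE0016	GENE0018	GENE0023	GENE0028
RANDOM_009	na	GENE0001	GENE0006	GENE0010	GENE0012	GENE0015	GENE0021	GENE0022	GENE0030	GENE0037
RANDOM_010	na	GENE0008	GENE0009	GENE0014	GENE0019	GENE0028	GENE0031	GENE0036	GENE0040
RANDOM_011	na	GENE0002	GENE0003	GENE0007	GENE0011	GENE0013	GENE0025	GENE0037
RANDOM_012	na	GENE0004	GENE0007	GENE0010	GENE0018	GENE0020	GENE0024	GENE0025	GENE0029	GENE0036
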