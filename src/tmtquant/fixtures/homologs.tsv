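source	target
Gene0001	GENE0001
Gene0002	GENE0002
Gene0003	GENE0003
Gene0004	GENE0004
Gene0005	GENE0005
Gene0006	GENE0006
Gene0007	GENE0007
Gene0008	GENE0008
Gene0009	GENE0009
Gene0010	GENE0010
Gene0011	GENE0011
Gene0012	GENE0012
Gene0013	GENE0013
Gene0014	GENE0014
Gene0015	GENE0015
Gene0016	GENE0016
Gene0017	GENE0017
Gene0018	GENE0018
Gene0019	GENE0019
Gene0020	GENE0020
Gene0021	GENE0021
Gene0022	GENE0022
Gene0023	GENE0023
Gene0024	GENE0024
Gene0025	GENE0025
Gene0026	GENE0026
Gene0027	GENE0027
Gene0028	GENE0028
Gene0029	GENE0029
Gene0030	GENE0030
Gene0031	GENE0031
Gene0032	GENE0032
Gene0033	GENE0033
Gene0034	GENE0034
Gene0035	GENE0035
Gene0036	GENE0036
Gene0037	GENE0037
Gene0038	GENE0038
Gene0039	GENE0039
Gene0040	GENE0040
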