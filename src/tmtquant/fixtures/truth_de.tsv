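gene	is_de	sign	effect	affected_groups
GENE0001	False	0.0	0.0	
GENE0002	False	0.0	0.0	
GENE0003	False	0.0	0.0	
GENE0004	False	0.0	0.0	
GENE0005	False	0.0	0.0	
GENE0006	True	1.0	1.5	tnbc;spindle;squamous;sarcomatoid
GENE0007	False	0.0	0.0	
GENE0008	True	1.0	1.5	tnbc;spindle;squamous;sarcomatoid
GENE0009	False	0.0	0.0	
GENE0010	False	0.0	0.0	
GENE0011	True	1.0	1.5	tnbc;spindle;squamous;sarcomatoid
GENE0012	False	0.0	0.0	
GENE0013	True	-1.0	-1.5	tnbc;spindle;squamous;sarcomatoid
GENE0014	False	0.0	0.0	
GENE0015	True	-1.0	-1.5	tnbc;spindle;squamous;sarcomatoid
GENE0016	False	0.0	0.0	
GENE0017	False	0.0	0.0	
GENE0018	False	0.0	0.0	
GENE0019	True	-1.0	-1.5	tnbc;spindle;squamous;sarcomatoid
GENE0020	False	0.0	0.0	
GENE0021	True	-1.0	-1.5	tnbc;spindle;squamous;sarcomatoid
GENE0022	False	0.0	0.0	
GENE0023	False	0.0	0.0	
GENE0024	False	0.0	0.0	
GENE0025	False	0.0	0.0	
GENE0026	False	0.0	0.0	
GENE0027	False	0.0	0.0	
GENE0028	False	0.0	0.0	
GENE0029	True	-1.0	-1.5	tnbc;spindle;squamous;sarcomatoid
GENE0030	False	0.0	0.0	
GENE0031	False	0.0	0.0	
GENE0032	False	0.0	0.0	
GENE0033	True	-1.0	-1.5	tnbc;spindle;squamous;sarcomatoid
GENE0034	False	0.0	0.0	
GENE0035	False	0.0	0.0	
GENE0036	False	0.0	0.0	
GENE0037	True	-1.0	-1.5	tnbc;spindle;squamous;sarcomatoid
GENE0038	False	0.0	0.0	
GENE0039	False	0.0	0.0	
GENE0040	False	0.0	0.0	
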