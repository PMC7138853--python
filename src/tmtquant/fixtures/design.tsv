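plex_id	channel	sample_id	is_reference
plex1	channel_126	normal_01	False
plex1	channel_127N	normal_04	False
plex1	channel_127C	tnbc_01	False
plex1	channel_128N	tnbc_04	False
plex1	channel_128C	spindle_01	False
plex1	channel_129N	spindle_04	False
plex1	channel_129C	squamous_01	False
plex1	channel_130N	squamous_04	False
plex1	channel_130C	sarcomatoid_03	False
plex1	channel_131	ref_plex1	True
plex2	channel_126	normal_02	False
plex2	channel_127N	normal_05	False
plex2	channel_127C	tnbc_02	False
plex2	channel_128N	tnbc_05	False
plex2	channel_128C	spindle_02	False
plex2	channel_129N	spindle_05	False
plex2	channel_129C	squamous_02	False
plex2	channel_130N	sarcomatoid_01	False
plex2	channel_130C	sarcomatoid_04	False
plex2	channel_131	ref_plex2	True
plex3	channel_126	normal_03	False
plex3	channel_127N	normal_06	False
plex3	channel_127C	tnbc_03	False
plex3	channel_128N	tnbc_06	False
plex3	channel_128C	spindle_03	False
plex3	channel_129N	spindle_06	False
plex3	channel_129C	squamous_03	False
plex3	channel_130N	sarcomatoid_02	False
plex3	channel_130C	sarcomatoid_05	False
plex3	channel_131	ref_plex3	True
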