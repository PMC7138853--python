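sample_id	group	batch
normal_01	normal	plex1
normal_02	normal	plex2
normal_03	normal	plex3
normal_04	normal	plex1
normal_05	normal	plex2
normal_06	normal	plex3
tnbc_01	tnbc	plex1
tnbc_02	tnbc	plex2
tnbc_03	tnbc	plex3
tnbc_04	tnbc	plex1
tnbc_05	tnbc	plex2
tnbc_06	tnbc	plex3
spindle_01	spindle	plex1
spindle_02	spindle	plex2
spindle_03	spindle	plex3
spindle_04	spindle	plex1
spindle_05	spindle	plex2
spindle_06	spindle	plex3
squamous_01	squamous	plex1
squamous_02	squamous	plex2
squamous_03	squamous	plex3
squamous_04	squamous	plex1
sarcomatoid_01	sarcomatoid	plex2
sarcomatoid_02	sarcomatoid	plex3
sarcomatoid_03	sarcomatoid	plex1
sarcomatoid_04	sarcomatoid	plex2
sarcomatoid_05	sarcomatoid	plex3
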