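name	abbreviation	hemisphere
corpus callosum	CC	L
caudoputamen	CP	L
anterior commissure olfactory limb	ACOL	L
pallidum	PAL	L
internal capsule	IntC	L
thalamus	TH	L
cerebellum	CB	L
superior colliculus motor related	SUC	L
ventricular systems	VS	L
hypothalamus	HY	L
inferior colliculus	IC	L
periaqueductal gray	PAG	L
isocortex	ICtx	L
cortical amygdalar area	COA	L
olfactory areas	OlfA	L
pons	P	L
midbrain reticular nucleus	RA	L
nucleus accumbens	NA	L
fimbria	F	L
anterior cingulate area	ACA	L
somatomotor areas	MO	L
somatosensory areas	SS	L
piriform area	PIR	L
taenia tecta	TT	L
accessory olfactory bulb glomerular layer	MOB_gl	L
accessory olfactory bulb granular layer	MOB_gr	L
retrohippocampal region	RHP	L
entorhinal area	EC	L
field CA1	CA1	L
field CA3	CA3	L
dentate gyrus	DG	L
field CA2	CA2	L
accessory olfactory bulb mitral layer	MOB_mi	L
striatum	STR	L
midbrain	MB	L
medulla	MY	L
corpus callosum	RCC	R
caudoputamen	RCP	R
anterior commissure olfactory limb	RACOL	R
pallidum	RPAL	R
internal capsule	RIC	R
thalamus	RTH	R
cerebellum	RCB	R
superior colliculus motor related	RSUC	R
ventricular systems	RVS	R
hypothalamus	RHY	R
inferior colliculus	RInfC	R
periaqueductal gray	RPAG	R
isocortex	RICtx	R
cortical amygdalar area	RCOA	R
olfactory areas	ROlfA	R
pons	RP	R
midbrain reticular nucleus	RRN	R
nucleus accumbens	RNA	R
fimbria	RF	R
anterior cingulate area	RACA	R
somatomotor areas	RMO	R
somatosensory areas	RSS	R
piriform area	RPIR	R
taenia tecta	RTT	R
accessory olfactory bulb glomerular layer	RAOB_gl	R
accessory olfactory bulb granular layer	RAOB_gr	R
retrohippocampal region	RRHP	R
entorhinal area	REC	R
field CA1	RCA1	R
field CA3	RCA3	R
dentate gyrus	RDG	R
field CA2	RCA2	R
accessory olfactory bulb mitral layer	RAOB_mi	R
striatum	RSTR	R
midbrain	RMB	R
medulla	RMY	R
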