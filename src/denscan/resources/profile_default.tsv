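# Default Denisovan directional prediction profile.
# Structure: 18 predictions over 12 cranial phenotypes; 12 tested against the
# AMH reference distribution and 6 against the Neanderthal one. The six
# Neanderthal-referenced predictions are the Den/Nea-derived clade
# differentiators (parietal breadth and maxilloalveolar length and glenoid
# fossa size greater in Denisovans; facial breadth, facial protrusion and
# malar flattening greater in Neanderthals). 14 predictions use linear (mm)
# measurements and 4 use nonlinear (angle/ratio) measurements. Measurement
# codes are synthetic stand-ins for the published measurement table, which is
# an external download; directions of the clade-distinguishing phenotypes
# follow their published descriptions.
prediction_id	phenotype_id	measurement_id	reference_group	direction	lineage_origin	measurement_class
P01	parietal_breadth	XPB	AMH	1	NEA_DEN_ANCESTOR	LINEAR
P02	parietal_breadth	XPB	NEANDERTHAL	1	DEN_DERIVED	LINEAR
P03	maxilloalveolar_length	MAL	AMH	1	NEA_DEN_ANCESTOR	LINEAR
P04	maxilloalveolar_length	MAL	NEANDERTHAL	1	DEN_DERIVED	LINEAR
P05	facial_breadth	ZYB	AMH	1	NEA_DEN_ANCESTOR	LINEAR
P06	facial_breadth	ZYB	NEANDERTHAL	-1	NEA_DERIVED	LINEAR
P07	facial_protrusion	FPA	AMH	1	NEA_DEN_ANCESTOR	NONLINEAR
P08	facial_protrusion	FPA	NEANDERTHAL	-1	NEA_DERIVED	NONLINEAR
P09	glenoid_fossa_size	GFA	AMH	1	NEA_DEN_ANCESTOR	LINEAR
P10	glenoid_fossa_size	GFA	NEANDERTHAL	1	DEN_DERIVED	LINEAR
P11	malar_flattening	MFA	AMH	1	NEA_DEN_ANCESTOR	NONLINEAR
P12	malar_flattening	MFA	NEANDERTHAL	-1	NEA_DERIVED	NONLINEAR
P13	facial_height	NPH	AMH	1	NEA_DEN_ANCESTOR	LINEAR
P14	calvarial_curvature	CCH	AMH	-1	AMH_DERIVED	LINEAR
P15	forehead_height	FRH	AMH	-1	AMH_DERIVED	LINEAR
P16	glabellar_protrusion	GLP	AMH	1	NEA_DEN_ANCESTOR	LINEAR
P17	cranial_base_area	CBA	AMH	1	NEA_DEN_ANCESTOR	LINEAR
P18	vault_height	BBH	AMH	-1	AMH_DERIVED	LINEAR
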