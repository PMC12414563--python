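roi	label	hemisphere	lobe	cluster
Banks of superior temporal sulcus	BK_l	L	Temporal	temporo-central
Caudal anterior cingulate	cAC_l	L	Frontal	frontal
Caudal middle frontal	cMF_l	L	Frontal	frontal
Cuneus	CU_l	L	Occipital	posterior
Entorhinal	EN_l	L	Temporal	temporo-central
Frontal pole	FP_l	L	Frontal	frontal
Fusiform	FU_l	L	Temporal	temporo-central
Inferior parietal	IP_l	L	Parietal	posterior
Inferior temporal	IT_l	L	Temporal	temporo-central
Insula	IN_l	L	Parietal	temporo-central
Isthmus cingulate	IST_l	L	Parietal	temporo-central
Lateral occipital	LO_l	L	Occipital	posterior
Lateral orbitofrontal	lOF_l	L	Frontal	frontal
Lingual	LG_l	L	Occipital	posterior
Medial orbitofrontal	mOF_l	L	Frontal	frontal
Middle temporal	MT_l	L	Temporal	temporo-central
Paracentral	PAC_l	L	Frontal	temporo-central
Parahippocampal	PH_l	L	Temporal	temporo-central
Pars opercularis	pOP_l	L	Frontal	frontal
Pars orbitalis	pOR_l	L	Frontal	frontal
Pars triangularis	pTR_l	L	Frontal	frontal
Pericalcarine	PCL_l	L	Occipital	posterior
Postcentral	POC_l	L	Parietal	temporo-central
Posterior cingulate	PCG_l	L	Parietal	posterior
Precentral	PRC_l	L	Frontal	temporo-central
Precuneus	PCU_l	L	Parietal	posterior
Rostral anterior cingulate	rAC_l	L	Frontal	frontal
Rostral middle frontal	rMF_l	L	Frontal	frontal
Superior frontal	SF_l	L	Frontal	frontal
Superior parietal	SP_l	L	Parietal	posterior
Superior temporal	ST_l	L	Temporal	temporo-central
Supramarginal	SMG_l	L	Parietal	posterior
Temporal pole	TP_l	L	Temporal	temporo-central
Transverse temporal	TT_l	L	Temporal	temporo-central
Banks of superior temporal sulcus	BK_r	R	Temporal	temporo-central
Caudal anterior cingulate	cAC_r	R	Frontal	frontal
Caudal middle frontal	cMF_r	R	Frontal	frontal
Cuneus	CU_r	R	Occipital	posterior
Entorhinal	EN_r	R	Temporal	temporo-central
Frontal pole	FP_r	R	Frontal	frontal
Fusiform	FU_r	R	Temporal	temporo-central
Inferior parietal	IP_r	R	Parietal	posterior
Inferior temporal	IT_r	R	Temporal	temporo-central
Insula	IN_r	R	Parietal	temporo-central
Isthmus cingulate	IST_r	R	Parietal	temporo-central
Lateral occipital	LO_r	R	Occipital	posterior
Lateral orbitofrontal	lOF_r	R	Frontal	frontal
Lingual	LG_r	R	Occipital	posterior
Medial orbitofrontal	mOF_r	R	Frontal	frontal
Middle temporal	MT_r	R	Temporal	temporo-central
Paracentral	PAC_r	R	Frontal	temporo-central
Parahippocampal	PH_r	R	Temporal	temporo-central
Pars opercularis	pOP_r	R	Frontal	frontal
Pars orbitalis	pOR_r	R	Frontal	frontal
Pars triangularis	pTR_r	R	Frontal	frontal
Pericalcarine	PCL_r	R	Occipital	posterior
Postcentral	POC_r	R	Parietal	temporo-central
Posterior cingulate	PCG_r	R	Parietal	posterior
Precentral	PRC_r	R	Frontal	temporo-central
Precuneus	PCU_r	R	Parietal	posterior
Rostral anterior cingulate	rAC_r	R	Frontal	frontal
Rostral middle frontal	rMF_r	R	Frontal	frontal
Superior frontal	SF_r	R	Frontal	frontal
Superior parietal	SP_r	R	Parietal	posterior
Superior temporal	ST_r	R	Temporal	temporo-central
Supramarginal	SMG_r	R	Parietal	posterior
Temporal pole	TP_r	R	Temporal	temporo-central
Transverse temporal	TT_r	R	Temporal	temporo-central
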