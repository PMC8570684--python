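region,abbreviation,module,pc,wmdz
Agranular insular area posterior part,AIp,1,0.03,0.12
Agranular insular area ventral part,AIv,4,0.43,0.85
Anterior cingulate area dorsal part,ACAd,1,0.17,0.87
Anterior cingulate area ventral part,ACAv,1,0.22,0.94
Anterior olfactory nucleus,AON,5,0.42,0.27
Anterolateral visual area,VISal,1,0.38,-0.12
Anteromedial visual area,VISam,2,0.57,0.97
Cortical amygdalar area posterior part,COAp,1,0.12,-0.46
Dentate gyrus,DG,2,0.58,0.99
Dorsal auditory area,AUDd,1,0.2,0.52
Dorsal peduncular area,DP,4,0.49,0.33
Ectorhinal area,ECT,1,0.13,0.78
Entorhinal area lateral part,ENTl,1,0.28,-1.5
Entorhinal area medial part,ENTm,4,0.57,-0.12
Fasciola cinerea,FC,1,0.25,-0.35
Field CA1,CA1,4,0.34,-0.11
Field CA2,CA2,4,0.36,0.33
Field CA3,CA3,4,0.44,0.8
Frontal pole cerebral cortex,FRP,5,0.49,-2.12
Gustatory areas,GU,1,0.44,-0.4
Induseum griseum,IG,3,0.47,-1.01
Infralimbic area,ILA,4,0.42,0.66
Lateral visual area,VISl,1,0.38,0.27
Nucleus of the lateral olfactory tract,NLOT,4,0.41,-1.16
Orbital area lateral part,ORBl,5,0.44,0.67
Orbital area medial part,ORBm,4,0.48,-2.31
Orbital area ventrolateral part,ORBvl,5,0.46,0.66
Parasubiculum,PAR,4,0.59,0.18
Perirhinal area,PERI,1,0.13,1.02
Piriform area,PIR,1,0.0,0.11
Piriform-amygdalar area,PAA,1,0.11,-2.62
Posterior auditory area,AUDpo,1,0.12,0.95
Posterolateral visual area,VISpl,2,0.55,0.98
Posteromedial visual area,VISpm,1,0.38,-0.12
Postpiriform transition area,TR,1,0.1,0.58
Postsubiculum,POST,1,0.34,0.58
Prelimbic area,PL,1,0.16,-1.81
Presubiculum,PRE,1,0.27,0.69
Primary auditory area,AUDp,1,0.07,0.85
Primary motor area,MOp,4,0.43,0.82
Primary somatosensory area barrel field,SSp-bfd,5,0.43,0.58
Primary somatosensory area lower limb,SSp-ll,4,0.44,1.12
Primary somatosensory area mouth,SSp-m,4,0.61,-0.75
Primary somatosensory area nose,SSp-n,4,0.54,0.67
Primary somatosensory area trunk,SSp-tr,4,0.48,0.7
Primary somatosensory area upper limb,SSp-ul,4,0.44,0.26
Primary visual area,VISp,4,0.5,0.56
Retrosplenial area dorsal part,RSPd,1,0.26,0.3
Retrosplenial area lateral agranular part,RSPagl,1,0.21,0.67
Retrosplenial area ventral part,RSPv,1,0.2,0.41
Secondary motor area,MOs,4,0.55,0.27
Subiculum,SUB,2,0.66,0.97
Supplemental somatosensory area,SSs,1,0.22,0.73
Taenia tecta,TT,4,0.53,0.65
Temporal association areas,TEa,1,0.14,0.93
Ventral auditory area,AUDv,1,0.09,0.85
Visceral area,VISC,1,0.09,0.9
Basolateral amygdalar nucleus,BLA,1,0.25,0.71
Claustrum,CLA,1,0.18,1.06
Endopiriform nucleus,EP,1,0.1,-0.96
Lateral amygdalar nucleus,LA,1,0.24,0.36
Posterior amygdalar nucleus,PA,4,0.35,0.54
Anterior amygdalar area,AAA,4,0.52,0.86
Bed nucleus of the accessory olfactory tract,BA,5,0.13,-0.68
Caudoputamen,CP,2,0.61,-0.17
Central amygdalar nucleus,CEA,1,0.36,-0.01
Fundus of striatum,FS,2,0.59,0.47
Intercalated amygdalar nucleus,IA,1,0.29,0.46
Lateral septal complex,LSX,1,0.22,-1.88
Medial amygdalar nucleus,MEA,5,0.49,0.64
Nucleus accumbens,ACB,4,0.39,0.7
Olfactory tubercle,OT,4,0.39,-2.16
Septofimbrial nucleus,SF,1,0.16,-0.31
Bed nuclei of the stria terminalis,BST,5,0.49,0.65
Diagonal band nucleus,NDB,5,0.44,-0.33
Globus pallidus external segment,GPe,4,0.49,-2.31
Globus pallidus internal segment,GPi,4,0.45,0.27
Magnocellular nucleus,MA,4,0.41,0.43
Medial septal nucleus,MS,2,0.66,0.48
Substantia innominata,SI,5,0.46,0.14
Triangular nucleus of septum,TRS,3,0.49,0.28
Anterior group of the dorsal thalamus,ATN,4,0.6,-1.42
Anterodorsal nucleus,AD,3,0.53,-1.16
Anteroventral nucleus of thalamus,AV,1,0.53,-2.45
Central lateral nucleus of the thalamus,CL,2,0.67,-1.12
Central medial nucleus of the thalamus,CM,1,0.17,0.09
Dorsal part of the lateral geniculate complex,LGd,4,0.0,-2.07
Interanteromedial nucleus of the thalamus,IAM,1,0.27,-2.07
Intergeniculate leaflet of the lateral geniculate complex,IGL,3,0.5,1.16
Intermediodorsal nucleus of the thalamus,IMD,1,0.12,-0.71
Lateral dorsal nucleus of thalamus,LD,5,0.47,0.64
Lateral habenula,LH,3,0.47,0.75
Lateral posterior nucleus of the thalamus,LP,5,0.44,-2.94
Medial geniculate complex,MG,1,0.22,0.81
Medial habenula,MH,3,0.38,1.19
Mediodorsal nucleus of thalamus,MD,1,0.23,0.03
Nucleus of reuniens,RE,2,0.67,0.86
Paracentral nucleus,PCN,4,0.58,0.66
Parafascicular nucleus,PF,2,0.68,-0.14
Parataenial nucleus,PT,3,0.4,-0.61
Paraventricular nucleus of the thalamus,PVT,3,0.46,-1.06
Peripeduncular nucleus,PP,1,0.41,-1.81
Posterior complex of the thalamus,PO,5,0.45,0.26
Posterior limiting nucleus of the thalamus,POL,1,0.21,-0.13
Reticular nucleus of the thalamus,RT,4,0.25,-0.76
Submedial nucleus of the thalamus,SMT,4,0.45,0.72
Subparafascicular nucleus,SPF,1,0.25,0.99
Thalamus sensory-motor cortex related,DORsm,1,0.2,-0.83
Ventral anterior-lateral complex of the thalamus,VAL,5,0.46,0.27
Ventral medial nucleus of the thalamus,VM,4,0.45,0.06
Ventral part of the lateral geniculate complex,LGv,1,0.21,0.44
Ventral posterior complex of the thalamus,VP,5,0.48,0.26
Ventral posterolateral nucleus of the thalamus,VPL,1,0.12,-2.84
Anterior hypothalamic nucleus,AHN,5,0.44,0.51
Anterodorsal preoptic nucleus,ADP,4,0.4,0.58
Anteroventral periventricular nucleus,AVPV,4,0.38,-0.22
Anteroventral preoptic nucleus,AVP,4,0.3,0.05
Arcuate hypothalamic nucleus,ARH,2,0.49,-0.42
Dorsal premammillary nucleus,PMd,2,0.64,0.5
Dorsomedial nucleus of the hypothalamus,DMH,2,0.61,0.75
Lateral hypothalamic area,LHA,4,0.44,-0.06
Lateral preoptic area,LPO,4,0.4,0.85
Mammillary body,MBO,1,0.39,-0.3
Medial preoptic area,MPO,4,0.4,0.81
Medial preoptic nucleus,MPN,5,0.45,0.5
Median preoptic nucleus,MEPO,4,0.29,-1.51
Parastrial nucleus,PS,4,0.45,1.11
Parasubthalamic nucleus,PSTN,2,0.42,-0.99
Paraventricular hypothalamic nucleus,PVH,1,0.22,0.88
Paraventricular hypothalamic nucleus descending division,PVHd,2,0.65,0.72
Periventricular hypothalamic nucleus posterior part,PVp,1,0.34,0.21
Periventricular hypothalamic nucleus preoptic part,PVpo,4,0.21,-0.74
Periventricular zone,PVZ,1,0.35,-0.5
Posterior hypothalamic nucleus,PH,1,0.28,0.76
Preparasubthalamic nucleus,PST,4,0.45,-2.2
Retrochiasmatic area,RCH,4,0.45,0.98
Subparaventricular zone,SBPV,4,0.48,0.07
Subthalamic nucleus,STN,4,0.59,0.58
Suprachiasmatic nucleus,SCH,2,0.61,-2.32
Supramammillary nucleus,SUM,1,0.37,0.05
Supraoptic nucleus,SO,4,0.45,-2.1
Tuberal nucleus,TU,4,0.49,0.64
Ventrolateral preoptic nucleus,VLPO,1,0.22,-2.82
Ventromedial hypothalamic nucleus,VMH,4,0.49,0.77
Zona incerta,ZI,4,0.5,0.85
Anterior pretectal nucleus,APN,2,0.68,-0.63
Cuneiform nucleus,CUN,4,0.4,0.44
Inferior colliculus,IC,1,0.19,0.38
Interpeduncular nucleus,IPN,1,0.26,0.06
Medial pretectal area,MPT,1,0.33,-1.59
Midbrain reticular nucleus,MRN,1,0.37,0.26
Midbrain reticular nucleus retrorubral area,RR,1,0.26,-0.19
Nucleus of Darkschewitsch,ND,2,0.69,-2.09
Nucleus of the brachium of the inferior colliculus,NB,1,0.22,0.26
Nucleus of the optic tract,NOT,3,0.4,0.67
Nucleus of the posterior commissure,NPC,3,0.49,0.2
Olivary pretectal nucleus,OP,3,0.44,0.33
Parabigeminal nucleus,PBG,3,0.38,0.2
Pedunculopontine nucleus,PPN,1,0.21,1.08
Periaqueductal gray,PAG,1,0.15,0.78
Posterior pretectal nucleus,PPT,3,0.66,-2.16
Precommissural nucleus,PRC,3,0.46,1.21
Red nucleus,RN,1,0.17,0.68
Substantia nigra compact part,SNc,2,0.64,0.19
Substantia nigra reticular part,SNr,4,0.62,-0.15
Superior colliculus motor related,SCm,1,0.36,0.45
Superior colliculus sensory related,SCs,1,0.25,0.64
Ventral tegmental area,VTA,1,0.37,-0.33
Pons,P,1,0.18,1.06
Pons motor related,P-mot,1,0.26,0.75
Pontine reticular nucleus,PRNr,1,0.23,0.82
Vestibular nuclei,VNC,1,0.47,-1.51
Ansiform lobule,AN,1,0.25,0.84
Central lobule,CENT,1,0.2,0.76
Culmen,CUL,1,0.19,0.4
Paraflocculus,PFL,1,0.27,-0.03
Simple lobule,SIM,1,0.36,-0.48
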