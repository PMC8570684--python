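region,abbreviation,module,pc,wmdz
Agranular insular area posterior part,AIp,3,0.35,-0.48
Agranular insular area ventral part,AIv,3,0.15,0.56
Anterior cingulate area dorsal part,ACAd,3,0.22,0.49
Anterior cingulate area ventral part,ACAv,3,0.47,0.34
Anterior olfactory nucleus,AON,4,0.5,0.02
Anterolateral visual area,VISal,1,0.65,0.53
Anteromedial visual area,VISam,3,0.31,0.99
Cortical amygdalar area posterior part,COAp,7,0.72,-0.69
Dentate gyrus,DG,1,0.49,-0.46
Dorsal auditory area,AUDd,5,0.48,0.87
Dorsal peduncular area,DP,3,0.08,0.66
Ectorhinal area,ECT,5,0.58,-0.57
Entorhinal area lateral part,ENTl,5,0.4,0.89
Entorhinal area medial part,ENTm,5,0.63,0.2
Fasciola cinerea,FC,1,0.6,-0.26
Field CA1,CA1,1,0.52,-0.04
Field CA2,CA2,5,0.41,1.11
Field CA3,CA3,6,0.52,0.08
Frontal pole cerebral cortex,FRP,4,0.46,0.59
Gustatory areas,GU,3,0.26,-0.79
Induseum griseum,IG,2,0.64,-1.94
Infralimbic area,ILA,3,0.42,0.59
Lateral visual area,VISl,1,0.63,0.54
Nucleus of the lateral olfactory tract,NLOT,5,0.5,-1.57
Orbital area lateral part,ORBl,3,0.47,-0.09
Orbital area medial part,ORBm,3,0.29,-0.1
Orbital area ventrolateral part,ORBvl,3,0.25,-1.76
Parasubiculum,PAR,1,0.38,-0.78
Perirhinal area,PERI,5,0.44,0.75
Piriform area,PIR,3,0.66,-2.98
Piriform-amygdalar area,PAA,7,0.44,1.21
Posterior auditory area,AUDpo,5,0.32,1.25
Posterolateral visual area,VISpl,1,0.61,0.72
Posteromedial visual area,VISpm,3,0.46,0.19
Postpiriform transition area,TR,5,0.47,-0.83
Postsubiculum,POST,1,0.34,-0.78
Prelimbic area,PL,3,0.59,-2.32
Presubiculum,PRE,1,0.49,0.42
Primary auditory area,AUDp,5,0.09,0.94
Primary motor area,MOp,3,0.42,0.73
Primary somatosensory area barrel field,SSp-bfd,3,0.19,0.28
Primary somatosensory area lower limb,SSp-ll,3,0.41,0.76
Primary somatosensory area mouth,SSp-m,4,0.45,0.4
Primary somatosensory area nose,SSp-n,4,0.5,0.57
Primary somatosensory area trunk,SSp-tr,3,0.34,0.84
Primary somatosensory area upper limb,SSp-ul,3,0.04,0.97
Primary visual area,VISp,1,0.53,0.94
Retrosplenial area dorsal part,RSPd,3,0.47,0.22
Retrosplenial area lateral agranular part,RSPagl,3,0.49,-0.27
Retrosplenial area ventral part,RSPv,1,0.59,1.3
Secondary motor area,MOs,3,0.42,0.65
Subiculum,SUB,2,0.5,0.25
Supplemental somatosensory area,SSs,4,0.5,0.56
Taenia tecta,TT,3,0.25,-0.68
Temporal association areas,TEa,5,0.4,0.38
Ventral auditory area,AUDv,5,0.32,1.17
Visceral area,VISC,4,0.21,-2.23
Basolateral amygdalar nucleus,BLA,7,0.0,0.99
Claustrum,CLA,3,0.39,-1.94
Endopiriform nucleus,EP,7,0.5,-0.93
Lateral amygdalar nucleus,LA,5,0.28,-0.6
Posterior amygdalar nucleus,PA,2,0.57,0.18
Anterior amygdalar area,AAA,3,0.21,-1.32
Bed nucleus of the accessory olfactory tract,BA,5,0.62,-1.74
Caudoputamen,CP,3,0.46,-2.69
Central amygdalar nucleus,CEA,7,0.0,-0.01
Fundus of striatum,FS,1,0.49,-0.47
Intercalated amygdalar nucleus,IA,4,0.39,0.87
Lateral septal complex,LSX,3,0.43,0.6
Medial amygdalar nucleus,MEA,6,0.58,1.02
Nucleus accumbens,ACB,1,0.48,-1.18
Olfactory tubercle,OT,7,0.5,0.51
Septofimbrial nucleus,SF,3,0.46,0.44
Bed nuclei of the stria terminalis,BST,3,0.46,0.21
Diagonal band nucleus,NDB,7,0.62,0.39
Globus pallidus external segment,GPe,7,0.48,-2.08
Globus pallidus internal segment,GPi,5,0.39,0.38
Magnocellular nucleus,MA,5,0.31,-0.02
Medial septal nucleus,MS,3,0.47,0.29
Substantia innominata,SI,2,0.5,0.69
Triangular nucleus of septum,TRS,1,0.58,-0.37
Anterior group of the dorsal thalamus,ATN,1,0.5,-1.82
Anterodorsal nucleus,AD,1,0.62,-0.25
Anteroventral nucleus of thalamus,AV,3,0.33,-1.54
Central lateral nucleus of the thalamus,CL,3,0.48,0.09
Central medial nucleus of the thalamus,CM,4,0.29,0.91
Dorsal part of the lateral geniculate complex,LGd,5,0.13,0.17
Interanterodorsal nucleus of the thalamus,IAD,1,0.59,1.15
Interanteromedial nucleus of the thalamus,IAM,6,0.77,-1.38
Intergeniculate leaflet of the lateral geniculate complex,IGL,5,0.6,0.22
Intermediodorsal nucleus of the thalamus,IMD,4,0.75,-1.36
Lateral dorsal nucleus of thalamus,LD,3,0.34,0.94
Lateral habenula,LH,2,0.5,0.53
Lateral posterior nucleus of the thalamus,LP,1,0.47,-1.86
Medial geniculate complex,MG,2,0.5,0.88
Medial habenula,MH,4,0.18,0.55
Mediodorsal nucleus of thalamus,MD,3,0.51,-0.33
Nucleus of reuniens,RE,2,0.49,0.64
Paracentral nucleus,PCN,2,0.49,0.88
Parafascicular nucleus,PF,2,0.55,0.85
Parataenial nucleus,PT,6,0.82,-2.3
Paraventricular nucleus of the thalamus,PVT,4,0.18,0.49
Peripeduncular nucleus,PP,2,0.5,0.83
Posterior complex of the thalamus,PO,5,0.4,-1.44
Posterior limiting nucleus of the thalamus,POL,7,0.48,-0.86
Reticular nucleus of the thalamus,RT,5,0.5,0.77
Submedial nucleus of the thalamus,SMT,2,0.47,1.02
Subparafascicular nucleus,SPF,2,0.48,1.22
Thalamus sensory-motor cortex related,DORsm,2,0.53,-0.14
Ventral anterior-lateral complex of the thalamus,VAL,5,0.43,-1.98
Ventral medial nucleus of the thalamus,VM,2,0.57,-0.13
Ventral part of the lateral geniculate complex,LGv,6,0.59,0.18
Ventral posterior complex of the thalamus,VP,2,0.61,-1.67
Ventral posterolateral nucleus of the thalamus,VPL,5,0.54,0.28
Anterior hypothalamic nucleus,AHN,1,0.61,0.85
Anterodorsal preoptic nucleus,ADP,3,0.41,0.72
Anteroventral periventricular nucleus,AVPV,3,0.46,0.32
Anteroventral preoptic nucleus,AVP,7,0.49,0.16
Arcuate hypothalamic nucleus,ARH,2,0.63,-1.47
Dorsal premammillary nucleus,PMd,5,0.6,-1.76
Dorsomedial nucleus of the hypothalamus,DMH,1,0.49,-1.35
Lateral hypothalamic area,LHA,1,0.59,-0.01
Lateral preoptic area,LPO,3,0.28,1.02
Mammillary body,MBO,5,0.1,0.84
Medial preoptic area,MPO,4,0.77,-1.38
Medial preoptic nucleus,MPN,3,0.41,0.72
Median preoptic nucleus,MEPO,3,0.26,0.76
Parastrial nucleus,PS,1,0.65,0.47
Parasubthalamic nucleus,PSTN,1,0.53,1.06
Paraventricular hypothalamic nucleus,PVH,3,0.46,0.18
Paraventricular hypothalamic nucleus descending division,PVHd,1,0.72,-2.34
Periventricular hypothalamic nucleus posterior part,PVp,2,0.58,-0.54
Periventricular hypothalamic nucleus preoptic part,PVpo,3,0.33,0.84
Periventricular zone,PVZ,3,0.43,0.53
Posterior hypothalamic nucleus,PH,2,0.63,-1.46
Preparasubthalamic nucleus,PST,2,0.59,-0.72
Retrochiasmatic area,RCH,6,0.63,0.59
Subparaventricular zone,SBPV,3,0.46,0.36
Subthalamic nucleus,STN,2,0.58,-1.93
Suprachiasmatic nucleus,SCH,3,0.44,0.53
Supramammillary nucleus,SUM,3,0.16,1.01
Supraoptic nucleus,SO,3,0.28,-0.67
Tuberal nucleus,TU,2,0.56,0.42
Ventrolateral preoptic nucleus,VLPO,7,0.36,1.31
Ventromedial hypothalamic nucleus,VMH,2,0.61,-1.47
Zona incerta,ZI,6,0.56,0.11
Anterior pretectal nucleus,APN,1,0.52,-0.52
Cuneiform nucleus,CUN,1,0.63,0.99
Inferior colliculus,IC,1,0.53,0.95
Interpeduncular nucleus,IPN,2,0.61,-1.72
Medial pretectal area,MPT,1,0.63,-2.05
Midbrain reticular nucleus,MRN,2,0.48,0.43
Midbrain reticular nucleus retrorubral area,RR,1,0.5,0.44
Nucleus of Darkschewitsch,ND,1,0.49,-0.33
Nucleus of the brachium of the inferior colliculus,NB,2,0.59,-0.55
Nucleus of the optic tract,NOT,1,0.52,-1.41
Nucleus of the posterior commissure,NPC,1,0.5,0.04
Olivary pretectal nucleus,OP,3,0.47,0.12
Parabigeminal nucleus,PBG,6,0.54,1.0
Pedunculopontine nucleus,PPN,2,0.49,0.6
Periaqueductal gray,PAG,1,0.64,0.39
Posterior pretectal nucleus,PPT,2,0.5,0.52
Precommissural nucleus,PRC,1,0.64,0.72
Red nucleus,RN,2,0.6,-0.92
Substantia nigra compact part,SNc,2,0.5,0.69
Substantia nigra reticular part,SNr,6,0.57,0.13
Superior colliculus motor related,SCm,1,0.6,1.32
Superior colliculus sensory related,SCs,1,0.54,1.1
Ventral tegmental area,VTA,2,0.56,0.37
Pons,P,6,0.63,0.57
Pons motor related,P-mot,1,0.55,0.67
Pontine reticular nucleus,PRNr,1,0.65,0.52
Vestibular nuclei,VNC,1,0.58,1.16
Ansiform lobule,AN,5,0.6,0.3
Central lobule,CENT,2,0.51,1.22
Culmen,CUL,2,0.51,0.28
Paraflocculus,PFL,2,0.46,1.16
Simple lobule,SIM,2,0.47,0.98
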