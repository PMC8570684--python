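region,abbreviation,module,pc,wmdz
Agranular insular area posterior part,AIp,1,0.07,-0.69
Agranular insular area ventral part,AIv,1,0.22,-0.76
Anterior cingulate area dorsal part,ACAd,3,0.34,0.93
Anterior cingulate area ventral part,ACAv,1,0.21,-0.3
Anterior olfactory nucleus,AON,3,0.41,-0.32
Anterolateral visual area,VISal,1,0.09,0.74
Anteromedial visual area,VISam,1,0.05,0.8
Cortical amygdalar area posterior part,COAp,1,0.16,-0.72
Dentate gyrus,DG,1,0.02,0.36
Dorsal auditory area,AUDd,1,0.05,0.35
Dorsal peduncular area,DP,4,0.32,0.71
Ectorhinal area,ECT,1,0.01,1.37
Entorhinal area lateral part,ENTl,1,0.04,1.05
Entorhinal area medial part,ENTm,1,0.17,-0.58
Fasciola cinerea,FC,3,0.47,-0.19
Field CA1,CA1,1,0.02,0.71
Field CA2,CA2,1,0.02,-0.11
Field CA3,CA3,1,0.05,0.89
Frontal pole cerebral cortex,FRP,1,0.32,-1.86
Gustatory areas,GU,1,0.21,-0.85
Induseum griseum,IG,4,0.55,0.71
Infralimbic area,ILA,1,0.25,-1.28
Lateral visual area,VISl,1,0.0,1.11
Nucleus of the lateral olfactory tract,NLOT,1,0.18,-0.41
Orbital area lateral part,ORBl,1,0.1,0.66
Orbital area medial part,ORBm,1,0.07,0.39
Orbital area ventrolateral part,ORBvl,1,0.04,1.1
Parasubiculum,PAR,2,0.53,-0.16
Perirhinal area,PERI,1,0.05,0.61
Piriform area,PIR,1,0.0,0.47
Piriform-amygdalar area,PAA,1,0.17,-0.63
Posterior auditory area,AUDpo,1,0.07,0.11
Posterolateral visual area,VISpl,1,0.0,1.58
Posteromedial visual area,VISpm,1,0.13,-1.88
Postpiriform transition area,TR,1,0.1,0.52
Postsubiculum,POST,2,0.6,-0.47
Prelimbic area,PL,1,0.23,-1.08
Presubiculum,PRE,1,0.28,-1.55
Primary auditory area,AUDp,1,0.0,1.19
Primary motor area,MOp,1,0.12,0.37
Primary somatosensory area barrel field,SSp-bfd,1,0.07,0.31
Primary somatosensory area lower limb,SSp-ll,1,0.19,-0.44
Primary somatosensory area mouth,SSp-m,3,0.29,0.47
Primary somatosensory area nose,SSp-n,3,0.25,-0.72
Primary somatosensory area trunk,SSp-tr,1,0.02,1.01
Primary somatosensory area upper limb,SSp-ul,1,0.16,0.07
Primary visual area,VISp,1,0.06,0.92
Retrosplenial area dorsal part,RSPd,1,0.02,0.8
Retrosplenial area lateral agranular part,RSPagl,1,0.0,1.32
Retrosplenial area ventral part,RSPv,2,0.17,-0.53
Secondary motor area,MOs,3,0.32,0.95
Subiculum,SUB,1,0.22,-0.86
Supplemental somatosensory area,SSs,1,0.14,-1.08
Taenia tecta,TT,1,0.13,-0.63
Temporal association areas,TEa,1,0.01,1.19
Ventral auditory area,AUDv,1,0.02,0.81
Visceral area,VISC,1,0.12,-0.03
Basolateral amygdalar nucleus,BLA,1,0.03,0.83
Claustrum,CLA,1,0.08,-0.82
Endopiriform nucleus,EP,1,0.0,1.06
Lateral amygdalar nucleus,LA,1,0.07,-0.35
Posterior amygdalar nucleus,PA,1,0.14,-0.55
Anterior amygdalar area,AAA,1,0.0,0.83
Bed nucleus of the accessory olfactory tract,BA,2,0.42,0.84
Caudoputamen,CP,1,0.27,-1.88
Central amygdalar nucleus,CEA,1,0.06,0.13
Fundus of striatum,FS,1,0.19,-1.88
Intercalated amygdalar nucleus,IA,1,0.03,0.97
Lateral septal complex,LSX,1,0.2,-0.72
Medial amygdalar nucleus,MEA,1,0.24,-1.74
Nucleus accumbens,ACB,1,0.15,0.13
Olfactory tubercle,OT,1,0.0,1.23
Septofimbrial nucleus,SF,1,0.17,-0.31
Bed nuclei of the stria terminalis,BST,1,0.11,0.91
Diagonal band nucleus,NDB,1,0.17,-1.14
Globus pallidus external segment,GPe,1,0.28,-1.46
Globus pallidus internal segment,GPi,1,0.18,-1.3
Magnocellular nucleus,MA,1,0.12,0.87
Medial septal nucleus,MS,1,0.21,-1.35
Substantia innominata,SI,1,0.0,0.95
Triangular nucleus of septum,TRS,3,0.34,1.31
Anterior group of the dorsal thalamus,ATN,2,0.38,1.78
Anterodorsal nucleus,AD,3,0.48,-2.3
Anteroventral nucleus of thalamus,AV,3,0.29,0.0
Central lateral nucleus of the thalamus,CL,1,0.13,-1.96
Central medial nucleus of the thalamus,CM,1,0.16,-0.82
Dorsal part of the lateral geniculate complex,LGd,1,0.03,1.01
Interanterodorsal nucleus of the thalamus,IAD,1,0.11,-0.89
Interanteromedial nucleus of the thalamus,IAM,1,0.0,0.42
Intergeniculate leaflet of the lateral geniculate complex,IGL,1,0.12,-0.18
Intermediodorsal nucleus of the thalamus,IMD,3,0.36,-1.56
Lateral dorsal nucleus of thalamus,LD,1,0.12,0.47
Lateral habenula,LH,4,0.0,-1.41
Lateral posterior nucleus of the thalamus,LP,1,0.32,-2.3
Medial geniculate complex,MG,1,0.1,-0.86
Medial habenula,MH,3,0.47,0.46
Mediodorsal nucleus of thalamus,MD,2,0.55,0.82
Nucleus of reuniens,RE,1,0.19,-2.35
Paracentral nucleus,PCN,1,0.16,-1.09
Parafascicular nucleus,PF,2,0.45,0.18
Parataenial nucleus,PT,2,0.24,-0.2
Paraventricular nucleus of the thalamus,PVT,1,0.0,1.09
Peripeduncular nucleus,PP,1,0.03,-0.79
Posterior complex of the thalamus,PO,1,0.03,0.85
Posterior limiting nucleus of the thalamus,POL,1,0.02,-0.23
Reticular nucleus of the thalamus,RT,1,0.17,-1.27
Submedial nucleus of the thalamus,SMT,1,0.15,0.5
Subparafascicular nucleus,SPF,1,0.12,0.33
Thalamus sensory-motor cortex related,DORsm,1,0.07,0.3
Ventral anterior-lateral complex of the thalamus,VAL,1,0.13,-0.7
Ventral medial nucleus of the thalamus,VM,2,0.66,-0.94
Ventral part of the lateral geniculate complex,LGv,1,0.11,-0.02
Ventral posterior complex of the thalamus,VP,1,0.07,-0.5
Ventral posterolateral nucleus of the thalamus,VPL,2,0.4,-1.1
Anterior hypothalamic nucleus,AHN,1,0.06,1.22
Anterodorsal preoptic nucleus,ADP,1,0.0,1.28
Anteroventral periventricular nucleus,AVPV,2,0.54,1.62
Anteroventral preoptic nucleus,AVP,2,0.52,1.08
Arcuate hypothalamic nucleus,ARH,1,0.17,-0.98
Dorsal premammillary nucleus,PMd,1,0.06,1.26
Dorsomedial nucleus of the hypothalamus,DMH,1,0.21,-0.49
Lateral hypothalamic area,LHA,1,0.07,0.67
Lateral preoptic area,LPO,1,0.1,0.53
Mammillary body,MBO,1,0.22,-1.28
Medial preoptic area,MPO,1,0.02,0.83
Medial preoptic nucleus,MPN,1,0.15,-1.12
Median preoptic nucleus,MEPO,1,0.13,-1.07
Parastrial nucleus,PS,1,0.02,0.96
Parasubthalamic nucleus,PSTN,1,0.1,0.97
Paraventricular hypothalamic nucleus,PVH,1,0.22,-0.4
Paraventricular hypothalamic nucleus descending division,PVHd,1,0.13,0.22
Periventricular hypothalamic nucleus posterior part,PVp,1,0.24,-1.54
Periventricular hypothalamic nucleus preoptic part,PVpo,1,0.25,-0.91
Periventricular zone,PVZ,3,0.38,0.12
Posterior hypothalamic nucleus,PH,1,0.04,1.47
Preparasubthalamic nucleus,PST,1,0.06,-0.14
Retrochiasmatic area,RCH,1,0.06,0.7
Subparaventricular zone,SBPV,1,0.3,-1.46
Subthalamic nucleus,STN,2,0.48,-0.73
Suprachiasmatic nucleus,SCH,1,0.12,-0.77
Supramammillary nucleus,SUM,1,0.06,0.69
Supraoptic nucleus,SO,1,0.0,1.32
Tuberal nucleus,TU,1,0.0,1.4
Ventrolateral preoptic nucleus,VLPO,1,0.07,-1.56
Ventromedial hypothalamic nucleus,VMH,1,0.13,0.16
Zona incerta,ZI,1,0.11,-0.75
Anterior pretectal nucleus,APN,1,0.1,-0.21
Cuneiform nucleus,CUN,1,0.0,1.54
Inferior colliculus,IC,1,0.03,0.94
Interpeduncular nucleus,IPN,1,0.06,-0.2
Medial pretectal area,MPT,3,0.3,0.84
Midbrain reticular nucleus,MRN,1,0.0,1.08
Midbrain reticular nucleus retrorubral area,RR,1,0.09,1.03
Nucleus of Darkschewitsch,ND,1,0.05,-0.4
Nucleus of the brachium of the inferior colliculus,NB,1,0.0,1.6
Nucleus of the optic tract,NOT,1,0.07,0.98
Nucleus of the posterior commissure,NPC,2,0.36,0.33
Olivary pretectal nucleus,OP,1,0.21,-0.61
Parabigeminal nucleus,PBG,1,0.09,0.2
Pedunculopontine nucleus,PPN,1,0.05,0.9
Periaqueductal gray,PAG,1,0.12,0.7
Posterior pretectal nucleus,PPT,1,0.06,-1.07
Precommissural nucleus,PRC,2,0.24,-0.5
Red nucleus,RN,1,0.01,1.32
Substantia nigra compact part,SNc,1,0.01,1.18
Substantia nigra reticular part,SNr,1,0.0,1.23
Superior colliculus motor related,SCm,1,0.11,0.71
Superior colliculus sensory related,SCs,1,0.11,-0.05
Ventral tegmental area,VTA,1,0.11,0.26
Pons,P,1,0.01,1.03
Pons motor related,P-mot,1,0.21,-1.09
Pontine reticular nucleus,PRNr,1,0.02,0.98
Vestibular nuclei,VNC,2,0.19,-2.26
Ansiform lobule,AN,1,0.15,-1.44
Central lobule,CENT,1,0.2,-0.79
Culmen,CUL,2,0.56,0.82
Paraflocculus,PFL,1,0.17,-1.5
Simple lobule,SIM,2,0.41,-0.57
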