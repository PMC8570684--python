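region,abbreviation,module,pc,wmdz
Agranular insular area posterior part,AIp,1,0.0,-0.9
Agranular insular area ventral part,AIv,1,0.0,0.64
Anterior cingulate area dorsal part,ACAd,1,0.0,-0.08
Anterior cingulate area ventral part,ACAv,1,0.0,0.41
Anterior olfactory nucleus,AON,1,0.0,-2.01
Anterolateral visual area,VISal,1,0.0,0.65
Anteromedial visual area,VISam,1,0.08,-1.15
Cortical amygdalar area posterior part,COAp,1,0.09,-0.41
Dentate gyrus,DG,1,0.32,-1.31
Dorsal auditory area,AUDd,1,0.0,0.67
Dorsal peduncular area,DP,2,0.67,-0.41
Ectorhinal area,ECT,1,0.0,0.81
Entorhinal area lateral part,ENTl,1,0.0,0.7
Entorhinal area medial part,ENTm,1,0.0,-0.26
Fasciola cinerea,FC,2,0.38,-0.46
Field CA1,CA1,1,0.18,-1.45
Field CA2,CA2,1,0.1,-1.36
Field CA3,CA3,1,0.0,-0.84
Frontal pole cerebral cortex,FRP,2,0.43,-1.01
Gustatory areas,GU,1,0.07,-1.09
Induseum griseum,IG,1,0.0,0.05
Infralimbic area,ILA,1,0.13,-1.04
Lateral visual area,VISl,1,0.0,1.3
Nucleus of the lateral olfactory tract,NLOT,1,0.07,-1.03
Orbital area lateral part,ORBl,3,0.5,-0.59
Orbital area medial part,ORBm,1,0.18,-1.44
Orbital area ventrolateral part,ORBvl,2,0.63,-0.41
Parasubiculum,PAR,1,0.0,0.95
Perirhinal area,PERI,1,0.0,0.61
Piriform area,PIR,1,0.0,-0.1
Piriform-amygdalar area,PAA,1,0.0,0.11
Posterior auditory area,AUDpo,1,0.05,-0.25
Posterolateral visual area,VISpl,1,0.35,-1.44
Posteromedial visual area,VISpm,1,0.0,-0.29
Postpiriform transition area,TR,1,0.0,2.19
Postsubiculum,POST,1,0.0,0.92
Prelimbic area,PL,1,0.0,-1.01
Presubiculum,PRE,1,0.0,0.98
Primary auditory area,AUDp,1,0.0,1.01
Primary motor area,MOp,1,0.0,-0.94
Primary somatosensory area barrel field,SSp-bfd,1,0.0,-0.18
Primary somatosensory area lower limb,SSp-ll,1,0.08,-1.08
Primary somatosensory area mouth,SSp-m,1,0.0,-1.12
Primary somatosensory area nose,SSp-n,1,0.0,-0.26
Primary somatosensory area trunk,SSp-tr,1,0.07,-0.97
Primary somatosensory area upper limb,SSp-ul,1,0.07,-1.08
Primary visual area,VISp,1,0.41,-1.52
Retrosplenial area dorsal part,RSPd,1,0.17,-1.33
Retrosplenial area lateral agranular part,RSPagl,1,0.04,0.18
Retrosplenial area ventral part,RSPv,2,0.0,-1.56
Secondary motor area,MOs,1,0.0,-1.4
Subiculum,SUB,1,0.0,1.0
Supplemental somatosensory area,SSs,1,0.0,-1.37
Taenia tecta,TT,1,0.09,-1.18
Temporal association areas,TEa,1,0.0,0.66
Ventral auditory area,AUDv,1,0.0,0.15
Visceral area,VISC,1,0.07,-1.11
Basolateral amygdalar nucleus,BLA,1,0.0,0.35
Claustrum,CLA,1,0.0,0.54
Endopiriform nucleus,EP,1,0.0,0.93
Lateral amygdalar nucleus,LA,1,0.0,1.26
Posterior amygdalar nucleus,PA,1,0.0,0.01
Anterior amygdalar area,AAA,1,0.0,1.07
Bed nucleus of the accessory olfactory tract,BA,1,0.0,0.51
Caudoputamen,CP,1,0.0,0.87
Central amygdalar nucleus,CEA,1,0.0,1.21
Fundus of striatum,FS,1,0.06,-0.84
Intercalated amygdalar nucleus,IA,1,0.0,2.04
Lateral septal complex,LSX,1,0.06,-0.83
Medial amygdalar nucleus,MEA,1,0.06,-0.61
Nucleus accumbens,ACB,1,0.0,-0.05
Olfactory tubercle,OT,1,0.32,-1.28
Septofimbrial nucleus,SF,3,0.45,-0.71
Bed nuclei of the stria terminalis,BST,2,0.43,0.28
Diagonal band nucleus,NDB,1,0.05,-0.24
Globus pallidus external segment,GPe,1,0.0,-0.2
Globus pallidus internal segment,GPi,2,0.5,2.18
Magnocellular nucleus,MA,1,0.0,-0.13
Medial septal nucleus,MS,1,0.0,0.49
Substantia innominata,SI,1,0.0,0.66
Triangular nucleus of septum,TRS,2,0.61,0.15
Anterior group of the dorsal thalamus,ATN,2,0.0,-1.56
Anterodorsal nucleus,AD,3,0.45,-0.61
Anteroventral nucleus of thalamus,AV,2,0.48,0.85
Central lateral nucleus of the thalamus,CL,3,0.0,-0.03
Central medial nucleus of the thalamus,CM,1,0.0,-0.3
Dorsal part of the lateral geniculate complex,LGd,2,0.47,-0.9
Interanterodorsal nucleus of the thalamus,IAD,1,0.0,-0.67
Interanteromedial nucleus of the thalamus,IAM,1,0.0,-1.28
Intergeniculate leaflet of the lateral geniculate complex,IGL,1,0.0,1.8
Intermediodorsal nucleus of the thalamus,IMD,1,0.0,2.04
Lateral dorsal nucleus of thalamus,LD,3,0.0,0.81
Lateral habenula,LH,1,0.41,-1.97
Lateral posterior nucleus of the thalamus,LP,1,0.16,-1.32
Medial geniculate complex,MG,1,0.0,0.87
Medial habenula,MH,1,0.0,-0.19
Mediodorsal nucleus of thalamus,MD,1,0.0,0.08
Nucleus of reuniens,RE,1,0.0,1.27
Paracentral nucleus,PCN,3,0.5,-1.38
Parafascicular nucleus,PF,3,0.0,0.85
Parataenial nucleus,PT,1,0.0,0.74
Paraventricular nucleus of the thalamus,PVT,1,0.0,1.82
Peripeduncular nucleus,PP,1,0.0,0.33
Posterior complex of the thalamus,PO,3,0.0,1.48
Posterior limiting nucleus of the thalamus,POL,1,0.0,-0.12
Reticular nucleus of the thalamus,RT,1,0.04,-0.11
Submedial nucleus of the thalamus,SMT,2,0.0,-0.9
Subparafascicular nucleus,SPF,1,0.0,1.36
Thalamus sensory-motor cortex related,DORsm,1,0.0,0.57
Ventral anterior-lateral complex of the thalamus,VAL,3,0.45,-1.28
Ventral medial nucleus of the thalamus,VM,3,0.0,1.54
Ventral part of the lateral geniculate complex,LGv,1,0.0,1.48
Ventral posterior complex of the thalamus,VP,3,0.5,-0.68
Ventral posterolateral nucleus of the thalamus,VPL,1,0.0,0.54
Anterior hypothalamic nucleus,AHN,1,0.0,0.69
Anterodorsal preoptic nucleus,ADP,1,0.06,-0.84
Anteroventral periventricular nucleus,AVPV,1,0.0,1.34
Anteroventral preoptic nucleus,AVP,1,0.0,1.23
Arcuate hypothalamic nucleus,ARH,2,0.5,-0.32
Dorsal premammillary nucleus,PMd,1,0.07,-0.82
Dorsomedial nucleus of the hypothalamus,DMH,1,0.0,0.39
Lateral hypothalamic area,LHA,1,0.0,-1.22
Lateral preoptic area,LPO,1,0.04,0.14
Mammillary body,MBO,2,0.5,0.98
Medial preoptic area,MPO,1,0.0,0.53
Medial preoptic nucleus,MPN,1,0.0,0.75
Median preoptic nucleus,MEPO,1,0.0,-0.14
Parastrial nucleus,PS,1,0.0,0.86
Parasubthalamic nucleus,PSTN,1,0.0,0.82
Paraventricular hypothalamic nucleus,PVH,1,0.0,1.36
Paraventricular hypothalamic nucleus descending division,PVHd,1,0.0,0.75
Periventricular hypothalamic nucleus posterior part,PVp,1,0.11,-0.62
Periventricular hypothalamic nucleus preoptic part,PVpo,1,0.0,0.65
Periventricular zone,PVZ,1,0.0,0.14
Posterior hypothalamic nucleus,PH,1,0.0,0.52
Preparasubthalamic nucleus,PST,1,0.0,-0.08
Retrochiasmatic area,RCH,1,0.43,-1.79
Subparaventricular zone,SBPV,1,0.0,1.26
Subthalamic nucleus,STN,1,0.07,-0.83
Suprachiasmatic nucleus,SCH,1,0.44,-1.61
Supramammillary nucleus,SUM,1,0.0,-0.11
Supraoptic nucleus,SO,1,0.07,-0.73
Tuberal nucleus,TU,2,0.5,0.97
Ventrolateral preoptic nucleus,VLPO,2,0.49,1.53
Ventromedial hypothalamic nucleus,VMH,1,0.41,-1.83
Zona incerta,ZI,1,0.0,1.35
Anterior pretectal nucleus,APN,1,0.0,-0.98
Cuneiform nucleus,CUN,2,0.44,1.64
Inferior colliculus,IC,1,0.0,1.08
Interpeduncular nucleus,IPN,1,0.05,-0.36
Medial pretectal area,MPT,1,0.0,0.45
Midbrain reticular nucleus,MRN,1,0.0,0.65
Midbrain reticular nucleus retrorubral area,RR,1,0.0,1.08
Nucleus of Darkschewitsch,ND,2,0.6,0.27
Nucleus of the brachium of the inferior colliculus,NB,1,0.0,1.09
Nucleus of the optic tract,NOT,1,0.0,0.27
Nucleus of the posterior commissure,NPC,2,0.63,-0.23
Olivary pretectal nucleus,OP,1,0.1,-1.47
Parabigeminal nucleus,PBG,1,0.0,0.57
Pedunculopontine nucleus,PPN,1,0.0,0.86
Periaqueductal gray,PAG,1,0.0,-0.01
Posterior pretectal nucleus,PPT,2,0.63,-0.27
Precommissural nucleus,PRC,1,0.0,0.85
Red nucleus,RN,1,0.04,-0.18
Substantia nigra compact part,SNc,1,0.0,0.8
Substantia nigra reticular part,SNr,1,0.3,-1.69
Superior colliculus motor related,SCm,1,0.0,1.18
Superior colliculus sensory related,SCs,1,0.0,1.79
Ventral tegmental area,VTA,1,0.11,-1.43
Pons,P,1,0.14,-0.54
Pons motor related,P-mot,1,0.47,-1.84
Pontine reticular nucleus,PRNr,1,0.09,-0.34
Vestibular nuclei,VNC,3,0.0,1.21
Ansiform lobule,AN,3,0.5,-0.6
Central lobule,CENT,1,0.0,0.14
Culmen,CUL,1,0.0,0.23
Paraflocculus,PFL,2,0.64,0.22
Simple lobule,SIM,2,0.26,-1.03
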