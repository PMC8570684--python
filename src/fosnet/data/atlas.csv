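name,abbreviation,group
Agranular insular area posterior part,AIp,Cortical plate
Agranular insular area ventral part,AIv,Cortical plate
Anterior cingulate area dorsal part,ACAd,Cortical plate
Anterior cingulate area ventral part,ACAv,Cortical plate
Anterior olfactory nucleus,AON,Cortical plate
Anterolateral visual area,VISal,Cortical plate
Anteromedial visual area,VISam,Cortical plate
Cortical amygdalar area posterior part,COAp,Cortical plate
Dentate gyrus,DG,Cortical plate
Dorsal auditory area,AUDd,Cortical plate
Dorsal peduncular area,DP,Cortical plate
Ectorhinal area,ECT,Cortical plate
Entorhinal area lateral part,ENTl,Cortical plate
Entorhinal area medial part,ENTm,Cortical plate
Fasciola cinerea,FC,Cortical plate
Field CA1,CA1,Cortical plate
Field CA2,CA2,Cortical plate
Field CA3,CA3,Cortical plate
Frontal pole cerebral cortex,FRP,Cortical plate
Gustatory areas,GU,Cortical plate
Induseum griseum,IG,Cortical plate
Infralimbic area,ILA,Cortical plate
Lateral visual area,VISl,Cortical plate
Nucleus of the lateral olfactory tract,NLOT,Cortical plate
Orbital area lateral part,ORBl,Cortical plate
Orbital area medial part,ORBm,Cortical plate
Orbital area ventrolateral part,ORBvl,Cortical plate
Parasubiculum,PAR,Cortical plate
Perirhinal area,PERI,Cortical plate
Piriform area,PIR,Cortical plate
Piriform-amygdalar area,PAA,Cortical plate
Posterior auditory area,AUDpo,Cortical plate
Posterolateral visual area,VISpl,Cortical plate
Posteromedial visual area,VISpm,Cortical plate
Postpiriform transition area,TR,Cortical plate
Postsubiculum,POST,Cortical plate
Prelimbic area,PL,Cortical plate
Presubiculum,PRE,Cortical plate
Primary auditory area,AUDp,Cortical plate
Primary motor area,MOp,Cortical plate
Primary somatosensory area barrel field,SSp-bfd,Cortical plate
Primary somatosensory area lower limb,SSp-ll,Cortical plate
Primary somatosensory area mouth,SSp-m,Cortical plate
Primary somatosensory area nose,SSp-n,Cortical plate
Primary somatosensory area trunk,SSp-tr,Cortical plate
Primary somatosensory area upper limb,SSp-ul,Cortical plate
Primary visual area,VISp,Cortical plate
Retrosplenial area dorsal part,RSPd,Cortical plate
Retrosplenial area lateral agranular part,RSPagl,Cortical plate
Retrosplenial area ventral part,RSPv,Cortical plate
Secondary motor area,MOs,Cortical plate
Subiculum,SUB,Cortical plate
Supplemental somatosensory area,SSs,Cortical plate
Taenia tecta,TT,Cortical plate
Temporal association areas,TEa,Cortical plate
Ventral auditory area,AUDv,Cortical plate
Visceral area,VISC,Cortical plate
Basolateral amygdalar nucleus,BLA,Cortical subplate
Claustrum,CLA,Cortical subplate
Endopiriform nucleus,EP,Cortical subplate
Lateral amygdalar nucleus,LA,Cortical subplate
Posterior amygdalar nucleus,PA,Cortical subplate
Anterior amygdalar area,AAA,Striatum
Bed nucleus of the accessory olfactory tract,BA,Striatum
Caudoputamen,CP,Striatum
Central amygdalar nucleus,CEA,Striatum
Fundus of striatum,FS,Striatum
Intercalated amygdalar nucleus,IA,Striatum
Lateral septal complex,LSX,Striatum
Medial amygdalar nucleus,MEA,Striatum
Nucleus accumbens,ACB,Striatum
Olfactory tubercle,OT,Striatum
Septofimbrial nucleus,SF,Striatum
Bed nuclei of the stria terminalis,BST,Pallidum
Diagonal band nucleus,NDB,Pallidum
Globus pallidus external segment,GPe,Pallidum
Globus pallidus internal segment,GPi,Pallidum
Magnocellular nucleus,MA,Pallidum
Medial septal nucleus,MS,Pallidum
Substantia innominata,SI,Pallidum
Triangular nucleus of septum,TRS,Pallidum
Anterior group of the dorsal thalamus,ATN,Thalamus
Anterodorsal nucleus,AD,Thalamus
Anteroventral nucleus of thalamus,AV,Thalamus
Central lateral nucleus of the thalamus,CL,Thalamus
Central medial nucleus of the thalamus,CM,Thalamus
Dorsal part of the lateral geniculate complex,LGd,Thalamus
Interanterodorsal nucleus of the thalamus,IAD,Thalamus
Interanteromedial nucleus of the thalamus,IAM,Thalamus
Intergeniculate leaflet of the lateral geniculate complex,IGL,Thalamus
Intermediodorsal nucleus of the thalamus,IMD,Thalamus
Lateral dorsal nucleus of thalamus,LD,Thalamus
Lateral habenula,LH,Thalamus
Lateral posterior nucleus of the thalamus,LP,Thalamus
Medial geniculate complex,MG,Thalamus
Medial habenula,MH,Thalamus
Mediodorsal nucleus of thalamus,MD,Thalamus
Nucleus of reuniens,RE,Thalamus
Paracentral nucleus,PCN,Thalamus
Parafascicular nucleus,PF,Thalamus
Parataenial nucleus,PT,Thalamus
Paraventricular nucleus of the thalamus,PVT,Thalamus
Peripeduncular nucleus,PP,Thalamus
Posterior complex of the thalamus,PO,Thalamus
Posterior limiting nucleus of the thalamus,POL,Thalamus
Reticular nucleus of the thalamus,RT,Thalamus
Submedial nucleus of the thalamus,SMT,Thalamus
Subparafascicular nucleus,SPF,Thalamus
Thalamus sensory-motor cortex related,DORsm,Thalamus
Ventral anterior-lateral complex of the thalamus,VAL,Thalamus
Ventral medial nucleus of the thalamus,VM,Thalamus
Ventral part of the lateral geniculate complex,LGv,Thalamus
Ventral posterior complex of the thalamus,VP,Thalamus
Ventral posterolateral nucleus of the thalamus,VPL,Thalamus
Anterior hypothalamic nucleus,AHN,Hypothalamus
Anterodorsal preoptic nucleus,ADP,Hypothalamus
Anteroventral periventricular nucleus,AVPV,Hypothalamus
Anteroventral preoptic nucleus,AVP,Hypothalamus
Arcuate hypothalamic nucleus,ARH,Hypothalamus
Dorsal premammillary nucleus,PMd,Hypothalamus
Dorsomedial nucleus of the hypothalamus,DMH,Hypothalamus
Lateral hypothalamic area,LHA,Hypothalamus
Lateral preoptic area,LPO,Hypothalamus
Mammillary body,MBO,Hypothalamus
Medial preoptic area,MPO,Hypothalamus
Medial preoptic nucleus,MPN,Hypothalamus
Median preoptic nucleus,MEPO,Hypothalamus
Parastrial nucleus,PS,Hypothalamus
Parasubthalamic nucleus,PSTN,Hypothalamus
Paraventricular hypothalamic nucleus,PVH,Hypothalamus
Paraventricular hypothalamic nucleus descending division,PVHd,Hypothalamus
Periventricular hypothalamic nucleus posterior part,PVp,Hypothalamus
Periventricular hypothalamic nucleus preoptic part,PVpo,Hypothalamus
Periventricular zone,PVZ,Hypothalamus
Posterior hypothalamic nucleus,PH,Hypothalamus
Preparasubthalamic nucleus,PST,Hypothalamus
Retrochiasmatic area,RCH,Hypothalamus
Subparaventricular zone,SBPV,Hypothalamus
Subthalamic nucleus,STN,Hypothalamus
Suprachiasmatic nucleus,SCH,Hypothalamus
Supramammillary nucleus,SUM,Hypothalamus
Supraoptic nucleus,SO,Hypothalamus
Tuberal nucleus,TU,Hypothalamus
Ventrolateral preoptic nucleus,VLPO,Hypothalamus
Ventromedial hypothalamic nucleus,VMH,Hypothalamus
Zona incerta,ZI,Hypothalamus
Anterior pretectal nucleus,APN,Midbrain
Cuneiform nucleus,CUN,Midbrain
Inferior colliculus,IC,Midbrain
Interpeduncular nucleus,IPN,Midbrain
Medial pretectal area,MPT,Midbrain
Midbrain reticular nucleus,MRN,Midbrain
Midbrain reticular nucleus retrorubral area,RR,Midbrain
Nucleus of Darkschewitsch,ND,Midbrain
Nucleus of the brachium of the inferior colliculus,NB,Midbrain
Nucleus of the optic tract,NOT,Midbrain
Nucleus of the posterior commissure,NPC,Midbrain
Olivary pretectal nucleus,OP,Midbrain
Parabigeminal nucleus,PBG,Midbrain
Pedunculopontine nucleus,PPN,Midbrain
Periaqueductal gray,PAG,Midbrain
Posterior pretectal nucleus,PPT,Midbrain
Precommissural nucleus,PRC,Midbrain
Red nucleus,RN,Midbrain
Substantia nigra compact part,SNc,Midbrain
Substantia nigra reticular part,SNr,Midbrain
Superior colliculus motor related,SCm,Midbrain
Superior colliculus sensory related,SCs,Midbrain
Ventral tegmental area,VTA,Midbrain
Pons,P,Hindbrain
Pons motor related,P-mot,Hindbrain
Pontine reticular nucleus,PRNr,Hindbrain
Vestibular nuclei,VNC,Hindbrain
Ansiform lobule,AN,Cerebellum
Central lobule,CENT,Cerebellum
Culmen,CUL,Cerebellum
Paraflocculus,PFL,Cerebellum
Simple lobule,SIM,Cerebellum
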