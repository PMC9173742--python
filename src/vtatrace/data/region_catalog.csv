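name,full_name,locality,midline,vta_subnucleus,serotonergic_group
Cortex,anterior cortex,long_range,false,false,
NAcMed,nucleus accumbens medial shell,long_range,false,false,
NAcCore,nucleus accumbens core,long_range,false,false,
NAcLat,nucleus accumbens lateral shell,long_range,false,false,
DStr,dorsal striatum,long_range,false,false,
VP,ventral pallidum,long_range,false,false,
Septum,septum,long_range,false,false,
BNST,bed nucleus of the stria terminalis,long_range,false,false,
EAM,extended amygdala,long_range,false,false,
CeA,central amygdala,long_range,false,false,
GPe,globus pallidus external segment,long_range,false,false,
EP,entopeduncular nucleus,long_range,false,false,
ZI,zona incerta,long_range,false,false,
PO,preoptic nucleus,long_range,false,false,
PVH,paraventricular hypothalamus,long_range,false,false,
LH,lateral hypothalamus,long_range,false,false,
LHb,lateral habenula,long_range,false,false,
MHb,medial habenula,long_range,false,false,
DR,dorsal raphe nucleus,long_range,true,false,B7
LDT,laterodorsal tegmentum,long_range,false,false,
PBN,parabrachial nucleus,long_range,false,false,
DCN,deep cerebellar nuclei,long_range,false,false,
PBP,parabrachial pigmented nucleus of the VTA,local,false,true,
PN,paranigral nucleus of the VTA,local,false,true,
IF,interfascicular nucleus of the VTA,local,false,true,
Rli,rostral linear nucleus,local,false,true,
SNc,substantia nigra pars compacta,local,false,false,
SNr,substantia nigra pars reticulata,local,false,false,
SNl,substantia nigra pars lateralis,local,false,false,
RRF,retrorubral field,local,false,false,
IPN,interpeduncular nucleus,local,false,false,
mRT,midbrain reticular nucleus,local,false,false,B6
PAG,periaqueductal gray,local,false,false,
PnO,pontine reticular nucleus oral part,local,false,false,B5
PnC,pontine reticular nucleus caudal part,local,false,false,
PPTg,pedunculopontine tegmental nucleus,local,false,false,
SPTg,subpeduncular tegmental nucleus,local,false,false,B9
SubB,subbrachial nucleus,local,false,false,
InC,interstitial nucleus of Cajal,local,false,false,
RI,rostral interstitial nucleus,local,false,false,
PT,pretectal area,local,false,false,
MnR,median raphe nucleus,local,true,false,B8
PMnR,paramedian raphe nucleus,local,false,false,
RMg,raphe magnus,local,true,false,B3
SuM,supramammillary nucleus,local,false,false,
SuMx,supramammillary decussation,local,false,false,
MM,medial mammillary nucleus,local,false,false,
RtTg,reticulotegmental nucleus,local,false,false,
ATg,anterior tegmental nucleus,local,false,false,
VTg,ventral tegmental nucleus,local,false,false,
SC,superior colliculus,local,false,false,
IC,inferior colliculus,local,false,false,
RPC,red nucleus parvocellular part,local,false,false,
PSth,parasubthalamic nucleus,local,false,false,
MiTg,microcellular tegmental nucleus,local,false,false,
DLL,dorsal nucleus of the lateral lemniscus,local,false,false,
MPL,medial paralemniscal nucleus,local,false,false,
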