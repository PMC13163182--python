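region_id,region_name,mni_x,mni_y,mni_z,network
ANG.L,Left Angular Gyrus,-45.3,-62.3,33.0,DMN
CER36.L,Left Cerebellum Lobules III-VI,-19.3,-54.3,-22.6,Cerebellum
CER36.R,Right Cerebellum Lobules III-VI,21.7,-54.1,-24.0,Cerebellum
CER12.L,Left Cerebellum Lobules I-II,-32.6,-71.9,-35.2,Cerebellum
CER12.R,Right Cerebellum Lobules I-II,35.3,-70.4,-36.2,Cerebellum
CER710.L,Left Cerebellum Lobules VII-X,-22.7,-55.7,-49.2,Cerebellum
CER710.R,Right Cerebellum Lobules VII-X,23.3,-57.5,-50.6,Cerebellum
PCC.L,Left Posterior Cingulate Cortex,-6.0,-44.5,22.0,DMN
PCC.R,Right Posterior Cingulate Cortex,6.4,-43.5,19.2,DMN
IFGtri.L,Left Inferior Frontal Gyrus (Triangular Part),-46.7,28.1,10.1,FPN
FUS.L,Left Fusiform Gyrus,-31.9,-42.4,-23.1,VN
HES.R,Right Heschl's Gyrus,45.1,-18.6,7.7,Auditory
IPL.R,Right Inferior Parietal Lobule,45.3,-47.5,47.2,Salience
SPL.R,Right Superior Parietal Lobule,24.8,-60.2,59.8,DAN
PCUN.L,Left Precuneus,-8.5,-57.4,45.5,DMN
PCUN.R,Right Precuneus,8.8,-57.4,41.3,DMN
SMA.R,Right Supplementary Motor Area,7.2,-0.9,58.7,SMN
THA.R,Right Thalamus,12.0,-19.3,5.2,Subcortical
VER,Cerebellar Vermis,1.2,-58.6,-20.1,Cerebellum
ANG.R,Right Angular Gyrus,45.3,-62.3,33.0,DMN
IFGtri.R,Right Inferior Frontal Gyrus (Triangular Part),46.7,28.1,10.1,FPN
FUS.R,Right Fusiform Gyrus,31.9,-42.4,-23.1,VN
HES.L,Left Heschl's Gyrus,-45.1,-18.6,7.7,Auditory
IPL.L,Left Inferior Parietal Lobule,-45.3,-47.5,47.2,Salience
SPL.L,Left Superior Parietal Lobule,-24.8,-60.2,59.8,DAN
SMA.L,Left Supplementary Motor Area,-7.2,-0.9,58.7,SMN
THA.L,Left Thalamus,-12.0,-19.3,5.2,Subcortical
PRE.L,Left Precentral Gyrus,-39,-6,51,SMN
PRE.R,Right Precentral Gyrus,39,-6,51,SMN
SFG.L,Left Superior Frontal Gyrus,-22,31,44,FPN
SFG.R,Right Superior Frontal Gyrus,22,31,44,FPN
MFG.L,Left Middle Frontal Gyrus,-38,33,34,FPN
MFG.R,Right Middle Frontal Gyrus,38,33,34,FPN
IFGop.L,Left Inferior Frontal Gyrus (Opercular Part),-50,15,21,Language
IFGop.R,Right Inferior Frontal Gyrus (Opercular Part),50,15,21,Language
ROL.L,Left Rolandic Operculum,-53,-8,15,SMN
ROL.R,Right Rolandic Operculum,53,-8,15,SMN
OLF.L,Left Olfactory Cortex,-8,15,-11,Limbic
OLF.R,Right Olfactory Cortex,8,15,-11,Limbic
SFGmed.L,Left Medial Superior Frontal Gyrus,-9,51,30,DMN
SFGmed.R,Right Medial Superior Frontal Gyrus,9,51,30,DMN
REC.L,Left Gyrus Rectus,-8,36,-18,Limbic
REC.R,Right Gyrus Rectus,8,36,-18,Limbic
INS.L,Left Insula,-39,6,2,Salience
INS.R,Right Insula,39,6,2,Salience
ACC.L,Left Anterior Cingulate Cortex,-8,37,16,Salience
ACC.R,Right Anterior Cingulate Cortex,8,37,16,Salience
MCC.L,Left Middle Cingulate Cortex,-8,-9,40,Salience
MCC.R,Right Middle Cingulate Cortex,8,-9,40,Salience
HIP.L,Left Hippocampus,-29,-21,-10,Limbic
HIP.R,Right Hippocampus,29,-21,-10,Limbic
PHG.L,Left Parahippocampal Gyrus,-25,-16,-21,Limbic
PHG.R,Right Parahippocampal Gyrus,25,-16,-21,Limbic
AMY.L,Left Amygdala,-27,1,-18,Limbic
AMY.R,Right Amygdala,27,1,-18,Limbic
CAL.L,Left Calcarine Cortex,-16,-73,9,VN
CAL.R,Right Calcarine Cortex,16,-73,9,VN
CUN.L,Left Cuneus,-14,-79,28,VN
CUN.R,Right Cuneus,14,-79,28,VN
LING.L,Left Lingual Gyrus,-16,-68,-5,VN
LING.R,Right Lingual Gyrus,16,-68,-5,VN
SOG.L,Left Superior Occipital Gyrus,-24,-81,31,VN
SOG.R,Right Superior Occipital Gyrus,24,-81,31,VN
MOG.L,Left Middle Occipital Gyrus,-37,-80,19,VN
MOG.R,Right Middle Occipital Gyrus,37,-80,19,VN
IOG.L,Left Inferior Occipital Gyrus,-38,-82,-8,VN
IOG.R,Right Inferior Occipital Gyrus,38,-82,-8,VN
POST.L,Left Postcentral Gyrus,-42,-23,49,SMN
POST.R,Right Postcentral Gyrus,42,-23,49,SMN
SMG.L,Left Supramarginal Gyrus,-58,-32,34,Salience
SMG.R,Right Supramarginal Gyrus,58,-32,34,Salience
PCL.L,Left Paracentral Lobule,-8,-25,70,SMN
PCL.R,Right Paracentral Lobule,8,-25,70,SMN
CAU.L,Left Caudate Nucleus,-15,12,9,Subcortical
CAU.R,Right Caudate Nucleus,15,12,9,Subcortical
PUT.L,Left Putamen,-28,5,2,Subcortical
PUT.R,Right Putamen,28,5,2,Subcortical
PAL.L,Left Pallidum,-21,0,0,Subcortical
PAL.R,Right Pallidum,21,0,0,Subcortical
STG.L,Left Superior Temporal Gyrus,-58,-22,7,Auditory
STG.R,Right Superior Temporal Gyrus,58,-22,7,Auditory
TPO.L,Left Temporal Pole,-40,15,-20,Limbic
TPO.R,Right Temporal Pole,40,15,-20,Limbic
MTG.L,Left Middle Temporal Gyrus,-57,-37,-1,Language
MTG.R,Right Middle Temporal Gyrus,57,-37,-1,Language
ITG.L,Left Inferior Temporal Gyrus,-54,-31,-22,VN
ITG.R,Right Inferior Temporal Gyrus,54,-31,-22,VN
OFC.L,Left Orbitofrontal Cortex,-31,50,-10,Limbic
OFC.R,Right Orbitofrontal Cortex,31,50,-10,Limbic
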