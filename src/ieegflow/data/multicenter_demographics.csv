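patient_id,center,n_seizures,n_channels,n_soz,implant
pt1,nih,4,84,10,ecog
pt2,nih,3,62,8,ecog
pt3,nih,2,97,37,ecog
pt6,nih,3,80,12,ecog
pt8,nih,3,59,16,ecog
pt10,nih,3,55,10,ecog
pt11,nih,4,78,24,ecog
pt13,nih,4,117,6,ecog
pt15,nih,4,71,18,ecog
pt16,nih,3,46,6,ecog
ummc002,ummc,3,49,10,ecog
ummc005,ummc,2,48,6,ecog
ummc008,ummc,2,50,23,ecog
ummc009,ummc,3,45,14,ecog
jh05,ummc,5,85,28,ecog
HUP065,hup,3,64,16,ecog
HUP070,hup,5,63,10,ecog
HUP074,hup,5,114,6,ecog
HUP082,hup,5,86,13,ecog
HUP087,hup,2,84,12,ecog
HUP088,hup,3,54,8,ecog
HUP089,hup,4,94,3,ecog
HUP094,hup,3,83,3,ecog
HUP097,hup,5,92,7,ecog
HUP105,hup,2,55,9,ecog
HUP106,hup,3,115,5,ecog
HUP107,hup,5,117,22,ecog
HUP111,hup,5,101,13,ecog
HUP116,hup,3,50,8,seeg
HUP117,hup,3,49,7,seeg
HUP123,hup,4,117,7,ecog
HUP126,hup,4,125,2,ecog
HUP130,hup,5,120,2,seeg
HUP139,hup,3,73,8,seeg
HUP140,hup,3,86,4,seeg
HUP141,hup,5,113,13,seeg
HUP142,hup,3,108,15,seeg
HUP144,hup,5,111,6,seeg
HUP146,hup,3,122,11,seeg
HUP148,hup,5,101,25,seeg
HUP150,hup,5,89,8,seeg
HUP157,hup,5,164,13,seeg
HUP160,hup,3,102,21,seeg
HUP163,hup,3,156,6,seeg
HUP164,hup,3,176,9,seeg
HUP177,hup,3,172,13,seeg
HUP180,hup,5,111,8,seeg
HUP185,hup,5,113,6,seeg
pt1,chum,11,97,6,grid_strip_depth
pt2,chum,5,104,8.6,grid_strip_depth
pt7,chum,9,61,7.1,grid_strip_depth
pt9,chum,4,105,8.5,grid_strip_depth
pt11,chum,7,91,6.4,grid_strip_depth
pt12,chum,3,88,4.6,grid_strip_depth
pt14,chum,4,73,14.5,grid_strip_depth
pt16,chum,5,101,3.8,grid_strip_depth
pt17,chum,4,114,1,grid_strip_depth
pt21,chum,5,111,6.8,grid_strip_depth
pt22,chum,5,108,4.2,grid_strip_depth
pt23,chum,2,99,8.5,grid_strip_depth
pt25,chum,3,113,1.3,grid_strip_depth
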