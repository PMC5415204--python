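variant,ddg,solvent_accessibility_pct,half_life_h,half_life_sd,nuclear,msh6_interaction,patient_found,temperature_sensitive
WT,0.0,,19,3,yes,yes,False,no
R39E,3.4,17.4,4,2,yes,yes,False,ts
A54Y,21.2,0.0,8,0.1,yes,yes,False,ts
L75K,3.0,6.1,5,2,yes,yes,False,ts
Y98C,2.5,19.8,13,2,yes,yes,True,ts_weak
L135Y,3.4,16.2,22,4,yes,yes,False,no
D180F,16.5,0.1,6,1,yes,yes,True,no
L187P,8.8,0.7,5,1,yes,no,True,no
C199R,5.5,0.0,5,1,partial,no,True,no
K228E,0.2,100,20,1,yes,yes,False,no
M253Y,-0.1,94.4,20,2,yes,yes,False,no
A266W,39.7,0.0,4,0.4,yes,weak,False,no
D283K,0.5,100,8,1,yes,yes,False,no
C333Y,21.7,0.3,5,0.4,partial,weak,True,no
A399K,9.4,0.3,11,1,yes,yes,False,no
D459I,2.4,20.6,13,1,yes,yes,False,no
E561V,0.0,78,20,5,yes,yes,False,no
D603N,1.0,3.8,6,2,partial,yes,True,no
P622T,3.7,0.0,10,2,partial,yes,True,cs
A649F,-0.3,100,16,3,yes,yes,False,no
G669D,12.7,10.3,7,1,yes,yes,True,no
G683R,9.8,0.0,7,3,partial,no,True,no
P696F,13.8,0.0,4,1,yes,weak,False,no
S743P,7.5,0.0,7,4,yes,yes,False,no
L851P,5.1,35.3,16,1,yes,yes,False,no
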