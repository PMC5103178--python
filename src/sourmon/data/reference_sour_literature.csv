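cell_type,culture_type,sour_lo_amol_cell_s,sour_hi_amol_cell_s
H460,adherent,30,30
A549,adherent,25,25
CHO,adherent,94,94
CHO,suspension,139,139
CHO,suspension,8,8
CHO,suspension,43,43
CHO,suspension,35,35
CHO,suspension,16,64
CHO,suspension,56,56
CHO,suspension,50,89
CHO,suspension,46,67
CHO,suspension,86,86
Fibroblast,adherent,60,60
Hepatocyte,adherent,240,330
hESC,adherent,110,112
hESC,adherent,1,4
hESC,adherent,1,1
hMSC,adherent,0.5,3
Hybridoma,adherent,49,49
Hybridoma,suspension,43,68
mESC,adherent,10,29
mESC,adherent,28,28
mESC,adherent,25,33
mESC,spheroids,40,40
mNSC,spheroids,31,31
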