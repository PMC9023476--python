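name,lod,units
il1a,0.19,pg/ml
il1b,0.26,pg/ml
il2,2.97,pg/ml
il4,2.12,pg/ml
il6,0.12,pg/ml
il8,0.36,pg/ml
il10,0.37,pg/ml
vegf,3.24,pg/ml
egf,1.04,pg/ml
tnfa,0.59,pg/ml
ifng,0.44,pg/ml
mcp1,3.53,pg/ml
h_fabp,2.94,ng/ml
adiponectin,0.18,ug/ml
folate,2.72,nmol/l
homocysteine,1.74,umol/l
vitamin_b12,73.8,pmol/l
hdl3,4,mg/dl
adma,0.938,umol/l
lrg1,0.0047,ug/ml
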