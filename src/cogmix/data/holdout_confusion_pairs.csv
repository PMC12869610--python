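diagnosis,predicted
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
CU,CU
MCI,CU
MCI,CU
MCI,CU
MCI,CU
MCI,CU
MCI,CU
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,MCI
MCI,Dem
MCI,Dem
MCI,Dem
MCI,Dem
MCI,Dem
Dem,MCI
Dem,MCI
Dem,MCI
Dem,MCI
Dem,MCI
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
Dem,Dem
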