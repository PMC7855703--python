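,tumor,necrosis,lymphocytes,stroma,fat,empty_space
tumor,1830,13,15,42,0,0
necrosis,50,1446,2,320,0,0
lymphocytes,4,2,705,10,0,0
stroma,42,120,20,3836,0,1
fat,0,0,0,0,562,5
empty_space,0,0,0,0,67,1257
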