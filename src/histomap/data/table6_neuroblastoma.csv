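,undifferentiated,necrosis,lymphocytes,differentiation,hemorrhage,empty_space,muscle,kidney
undifferentiated,1403,3,0,14,1,0,0,0
necrosis,13,1642,1,26,49,2,5,18
lymphocytes,6,5,1150,0,0,0,0,3
differentiation,0,0,0,1261,0,0,0,0
hemorrhage,1,7,0,0,1327,0,9,0
empty_space,0,2,0,0,0,560,3,2
muscle,0,2,0,0,1,0,1176,0
kidney,0,0,0,0,0,0,0,1176
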