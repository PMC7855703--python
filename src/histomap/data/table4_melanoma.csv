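,tumor,stroma,epidermis,lymphocytes,fat,empty_space
tumor,5286,10,7,8,0,0
stroma,9,986,0,0,2,0
epidermis,22,0,545,0,1,0
lymphocytes,0,0,1,821,0,0
fat,0,9,0,0,5603,3
empty_space,0,0,0,0,98,681
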