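,Item1,Item2,Item3,Item4,Item5,Item6,Item7,Item8,Item9,Item10
P371,1,1,0,1,0,1,0,1,0,1
P2754,1,1,1,1,1,1,0,0,0,1
P3716,0,0,1,0,0,1,1,1,0,1
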