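compound,target,ic50_uM,sem_uM
5n,AChE,4.24,
5n,BChE,22.00,
6aa,BChE,3.97,
galantamine,BChE,8.80,
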