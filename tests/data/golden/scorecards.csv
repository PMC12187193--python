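# config_hash=4c73b77bc50bc4bf
individual_id,score_16,score_10,score_high,total,phenotype
H01,4,4,4,12,high
I01,4,2,1,7,intermediate
L01,3,1,1,5,low
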