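example_id,as_16,as_10,as_high,score_16,score_10,score_high,total,phenotype
WX01,3.0,4.0,5.5,3,3,4,10,high
WX02,1.0,2.0,3.0,1,1,1,3,low
WX03,2.6,2.59,3.35,3,2,2,7,intermediate
WX04,3.45,4.77,5.05,4,4,4,12,high
WX05,2.6,2.0,3.0,3,1,1,5,low
WX06,1.75,3.68,4.2,2,3,3,8,intermediate
WX07,-0.5,6.0,4.5,1,4,3,8,intermediate
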