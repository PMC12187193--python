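# config_hash=4c73b77bc50bc4bf
individual_id,archetype,mass_kg,treatment_temp_c,true_smr,true_mmr,true_aerobic_scope
H01,high,1.1500381866418667,10.0,0.6539101633327609,6.097208891962093,5.4432987286293315
H01,high,1.1500381866418667,16.0,0.9911424675729861,7.263923173433792,6.272780705860806
H01,high,1.1500381866418667,21.0,1.4016871198856524,6.6607909742254146,5.259103854339762
I01,intermediate,1.2188277715008184,10.0,0.6463564267647075,3.6732631443348147,3.026906717570107
I01,intermediate,1.2188277715008184,16.0,0.979693143917732,5.257312373166105,4.277619229248373
I01,intermediate,1.2188277715008184,21.0,1.3854953310923932,4.007896903722166,2.622401572629773
L01,low,1.298200113373757,10.0,0.6382520392730856,1.1043023170921744,0.46605027781908887
L01,low,1.298200113373757,16.0,0.967409189535261,3.725801740554986,2.7583925510197247
L01,low,1.298200113373757,21.0,1.3681231962051303,1.3178442609948926,-0.050278935210237796
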