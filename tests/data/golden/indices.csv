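# config_hash=4c73b77bc50bc4bf
individual_id,treatment_temp_c,mass_kg,smr,mmr,aerobic_scope,smr_measured,mmr_measured,n_cycles_used,n_cycles_discarded,flags
H01,10.0,1.1500381866418667,0.6714431074914128,6.225383577421008,5.553940469929595,0.65291016333275,6.0535526584357005,15,0,
H01,16.0,1.1500381866418667,1.0182477967456562,7.418530485262836,6.400282688517179,0.9901424675729832,7.213766731359126,15,0,
H01,21.0,1.1500381866418667,1.4404458150851174,6.821361248907102,5.3809154338219845,1.4006871198856237,6.633080357046612,15,0,
I01,10.0,1.2188277715008184,0.6714396591127452,3.796005263980739,3.124565604867994,0.6453564267646961,3.6485428882466873,15,0,
I01,16.0,1.2188277715008184,1.0182487749017097,5.433879371262107,4.415630596360398,0.9786931439177228,5.222790949140617,15,0,
I01,21.0,1.2188277715008184,1.4404521820788785,4.154985493569379,2.7145333114905004,1.3844953310923493,3.993577911278584,15,0,
L01,10.0,1.298200113373757,0.6714357548824081,1.158637978586711,0.4872022237043028,0.6372520392730834,1.0996501292412326,15,0,
L01,16.0,1.298200113373757,1.0182496778528636,3.9018333782962222,2.8835837004433587,0.966409189535251,3.70318568700369,15,0,
L01,21.0,1.298200113373757,1.440458937264942,1.3932946812368552,-0.04716425602808674,1.367123196205101,1.3223601371690807,15,0,negative_aerobic_scope
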