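# config_hash=17e7af4b0ed66225
individual_id,archetype,mass_kg,treatment_temp_c,true_smr,true_mmr,true_aerobic_scope
H01,high,0.9514280811076798,10.0,0.6791807161427637,6.318071753844348,5.638891037701584
H01,high,0.9514280811076798,16.0,1.0294454631119832,7.428196254681608,6.398750791569625
H01,high,0.9514280811076798,21.0,1.4558557356564183,6.752449935795227,5.296594200138808
H02,high,1.2793313813167102,10.0,0.6401237326834497,5.777327712543194,5.137203979859744
H02,high,1.2793313813167102,16.0,0.9702461462447783,7.249458941719961,6.279212795475182
H02,high,1.2793313813167102,21.0,1.372135258859595,6.7505255799805095,5.378390321120915
H03,high,1.1681442336409935,10.0,0.6518703768891164,5.690330577360308,5.038460200471191
H03,high,1.1681442336409935,16.0,0.9880507294682107,7.3625400692555925,6.374489339787383
H03,high,1.1681442336409935,21.0,1.3973147419265737,7.007733622728486,5.610418880801912
I01,intermediate,1.0413099420241791,10.0,0.6670287247393779,3.3933872098019493,2.7263584850625713
I01,intermediate,1.0413099420241791,16.0,1.0110264884257794,5.702183757627013,4.691157269201233
I01,intermediate,1.0413099420241791,21.0,1.4298073718501823,4.699797576648338,3.2699902047981557
I02,intermediate,0.933246799094097,10.0,0.6818066578855637,3.4099492805858973,2.728142622700333
I02,intermediate,0.933246799094097,16.0,1.0334256465142364,5.449587124418963,4.416161477904726
I02,intermediate,0.933246799094097,21.0,1.4614845650046173,4.366834239636404,2.9053496746317866
I03,intermediate,0.9132298749509715,10.0,0.6847696721372823,3.6126665089832026,2.92789683684592
I03,intermediate,0.9132298749509715,16.0,1.0379167363023727,5.64878561561187,4.610868879309497
I03,intermediate,0.9132298749509715,21.0,1.4678359250928348,4.821419993038372,3.353584067945537
L01,low,0.9639294776419924,10.0,0.6774098188673062,1.1236661817444273,0.44625636287712117
L01,low,0.9639294776419924,16.0,1.0267612847739842,3.8338410124378184,2.8070797276638344
L01,low,0.9639294776419924,21.0,1.452059734246992,1.1790924245655645,-0.27296730968142763
L02,low,1.0234838972818248,10.0,0.6693362354772628,1.6197905634060874,0.9504543279288244
L02,low,1.0234838972818248,16.0,1.0145240206785924,3.62124328937906,2.6067192687004677
L02,low,1.0234838972818248,21.0,1.4347536293969476,1.6432252899119213,0.20847166051497368
L03,low,1.1956987496134768,10.0,0.648837862065178,0.7091166492638052,0.06027878719862727
L03,low,1.1956987496134768,16.0,0.9834542965113788,3.6479971137895197,2.6645428172781407
L03,low,1.1956987496134768,21.0,1.390814404100483,1.5657676031324286,0.17495319903194542
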