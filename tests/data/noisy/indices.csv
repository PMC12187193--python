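# config_hash=17e7af4b0ed66225
individual_id,treatment_temp_c,mass_kg,smr,mmr,aerobic_scope,smr_measured,mmr_measured,n_cycles_used,n_cycles_discarded,flags
H01,10.0,0.9514280811076798,0.6640187147970574,6.180785689293257,5.5167669744962,0.6711822636343144,6.247465075206956,13,2,
H01,16.0,0.9514280811076798,1.010135525608428,7.220651887541578,6.21051636193315,1.0210330425137395,7.298549530003425,15,0,
H01,21.0,0.9514280811076798,1.4347588074582507,6.744262563928635,5.309503756470384,1.4502372338306955,6.817020835904076,13,2,
H02,10.0,1.2793313813167102,0.6502596836192288,6.047392156892269,5.3971324732730395,0.6166391980506639,5.734722825146793,15,0,
H02,16.0,1.2793313813167102,1.009633513393992,7.614278678789361,6.604645165395369,0.9574322623835129,7.220596350199585,15,0,
H02,21.0,1.2793313813167102,1.3062621562463819,6.921618882310233,5.615356726063852,1.2387242647252454,6.5637492594410975,15,0,
H03,10.0,1.1681442336409935,0.6270343996104863,5.818908193607859,5.191873793997373,0.6063806585200645,5.627240522209977,15,0,
H03,16.0,1.1681442336409935,0.9690720471826635,7.503239611819167,6.534167564636503,0.9371520071132364,7.256092137329445,15,0,
H03,21.0,1.1681442336409935,1.391271280112076,7.134190310628848,5.742919030516772,1.3454445171404994,6.899198865730359,15,0,
I01,10.0,1.0413099420241791,0.6544084623653096,3.4616992640709503,2.8072908017056406,0.6487244603433591,3.4316319487045726,14,1,
I01,16.0,1.0413099420241791,0.9614052237928585,5.7851650796895235,4.8237598558966654,0.9530547369788571,5.734916814421956,15,0,
I01,21.0,1.0413099420241791,1.3473381315175885,4.691042991752761,3.343704860235172,1.3356355434487899,4.6502979534722275,13,2,
I02,10.0,0.933246799094097,0.6427770193216479,3.351932809046256,2.709155789724608,0.6524185981214409,3.402211402304206,12,3,
I02,16.0,0.933246799094097,0.9806250480856674,5.272205035980169,4.291579987894501,0.995334307113233,5.351287484131027,15,0,
I02,21.0,0.933246799094097,1.3323799328284125,4.232958033315475,2.900578100487062,1.352365473268525,4.296451900096056,12,3,
I03,10.0,0.9132298749509715,0.6023755757495222,3.507504596598025,2.905129020848503,0.6142747370287949,3.5767908767244703,14,1,
I03,16.0,0.9132298749509715,0.9634424342792194,5.547853633324748,4.584411199045529,0.9824740108741351,5.657444406580436,15,0,
I03,21.0,0.9132298749509715,1.38957097657121,4.883212103780946,3.493641127209736,1.4170201790702381,4.979673731248968,13,2,
L01,10.0,0.9639294776419924,0.6452586942213117,1.1482619337131683,0.5030032394918567,0.6503875784276162,1.1573889746182573,14,1,
L01,16.0,0.9639294776419924,0.9934162985266518,3.724707806494922,2.7312915079682702,1.0013125379875514,3.754313908997555,15,0,
L01,21.0,0.9639294776419924,1.2674726134432954,1.1843985721261212,-0.08307404131717415,1.2775472088377176,1.1938128476484031,14,1,negative_aerobic_scope
L02,10.0,1.0234838972818248,0.6013810804500337,1.6280783448871932,1.0266972644371595,0.5983802104031273,1.6199542922722807,14,1,
L02,16.0,1.0234838972818248,0.9791389723409519,3.564196194329208,2.5850572219882566,0.9742531039467255,3.546410983007202,15,0,
L02,21.0,1.0234838972818248,1.260418208979682,1.9594423204262934,0.6990241114466114,1.2541287672714858,1.9496647734445895,14,1,
L03,10.0,1.1956987496134768,0.6115496132433256,0.7818323619511531,0.1702827487078275,0.5884418943635884,0.7522904212159869,15,0,
L03,16.0,1.1956987496134768,0.9943316482196252,3.78746898770083,2.793137339481205,0.9567603118918516,3.6443575103353933,15,0,
L03,21.0,1.1956987496134768,1.3518559928336216,1.78047102201892,0.42861502918529837,1.3007754139700092,1.713195002282543,15,0,
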