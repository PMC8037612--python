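mouse,age_months,brain_npc,brain_avnd,mpz_npc,mpz_avnd,sgz_npc,sgz_avnd,other_npc,other_avnd,cms_npc,cms_avnd,rms_npc,rms_avnd,midlayer_npc,midlayer_avnd,sez_npc,sez_avnd,other_cms_npc,other_cms_avnd
2M-A,2,68010,193.3,45524,283.7,2732,45.5,19754,6.4,30607,357.3,3559,323.9,11358,72.7,14087,272.2,16520,429.9
2M-B,2,67636,173.7,44505,259.5,2570,40.5,20561,6.1,29571,330.0,3234,287.5,11700,73.5,13343,270.5,16228,378.8
4M-A,4,52489,127.4,32030,205.3,1554,23.7,18905,3.9,23019,241.9,3366,239.4,5645,36.1,11729,196.8,11290,288.6
4M-B,4,49359,137.5,30425,219.6,1581,25.6,17353,4.8,22012,254.9,3115,283.5,5298,35.3,10184,193.6,11828,307.7
8M-A,8,42711,82.5,19376,176.6,625,12.2,22710,4.9,14881,184.1,3021,220.0,1474,11.1,8010,159.1,6871,210.7
8M-B,8,40904,76.4,18901,160.7,613,12.8,21390,4.4,14969,170.5,2433,191.8,1499,11.4,7662,145.5,7307,196.7
12M-A,12,33200,48.4,12869,119.8,325,6.7,20006,3.8,10057,120.2,2136,153.5,676,6.3,5926,107.2,4131,139.0
12M-B,12,30453,45.2,11632,112.3,314,8.6,18507,3.8,9974,118.4,1067,113.8,591,6.3,6255,106.7,3719,138.1
30M-A,30,20269,18.5,4877,64.9,70,2.7,15322,4.2,3970,74.4,446,42.8,461,3.6,3337,76.4,633,63.9
30M-B,30,20215,13.9,4289,51.1,69,2.1,15857,4.0,3592,58.5,306,25.8,391,3.4,2644,57.9,948,60.0
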