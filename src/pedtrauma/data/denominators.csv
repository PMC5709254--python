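year,population_0_19,total_ed_discharges,vmt_millions
2006,82482488,,3012888
2007,82814893,,3049027
2008,83236036,,2992705
2009,83280391,,2975804
2010,83118264,,2985854
2011,82749431,,2968990
2012,82324415,,2988021
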