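zone_id,zone_name,belt,frost,p_octave,r_octave,agg_id,agg_name,color
1,Polar desert,polar,any,0.5,2.5,1,Polar desert,#f2f2f2
1,Polar desert,polar,any,1.5,1.5,1,Polar desert,#f2f2f2
1,Polar desert,polar,any,2.5,0.5,1,Polar desert,#f2f2f2
2,Dry tundra,subpolar,any,0.5,3.5,2,Tundra,#b8a7ce
3,Moist tundra,subpolar,any,1.5,2.5,2,Tundra,#b8a7ce
4,Wet tundra,subpolar,any,2.5,1.5,2,Tundra,#b8a7ce
5,Rain tundra,subpolar,any,3.5,0.5,2,Tundra,#b8a7ce
6,Boreal desert,boreal,any,0.5,4.5,3,Boreal desert,#d9c9a3
7,Boreal dry scrub,boreal,any,1.5,3.5,3,Boreal desert,#d9c9a3
8,Boreal moist forest,boreal,any,2.5,2.5,4,Boreal forest,#2f7e4a
9,Boreal wet forest,boreal,any,3.5,1.5,4,Boreal forest,#2f7e4a
10,Boreal rain forest,boreal,any,4.5,0.5,4,Boreal forest,#2f7e4a
11,Cool temperate desert,cool_temperate,any,0.5,5.5,5,Temperate desert,#e8d17f
12,Cool temperate desert scrub,cool_temperate,any,1.5,4.5,5,Temperate desert,#e8d17f
13,Cool temperate steppe,cool_temperate,any,2.5,3.5,6,Temperate steppe,#d9a75c
14,Cool temperate moist forest,cool_temperate,any,3.5,2.5,7,Temperate forest,#66b268
15,Cool temperate wet forest,cool_temperate,any,4.5,1.5,7,Temperate forest,#66b268
16,Cool temperate rain forest,cool_temperate,any,5.5,0.5,7,Temperate forest,#66b268
17,Warm temperate desert,warm_temperate,frost,0.5,6.5,5,Temperate desert,#e8d17f
18,Warm temperate desert scrub,warm_temperate,frost,1.5,5.5,5,Temperate desert,#e8d17f
19,Warm temperate thorn steppe,warm_temperate,frost,2.5,4.5,6,Temperate steppe,#d9a75c
20,Warm temperate dry forest,warm_temperate,frost,3.5,3.5,7,Temperate forest,#66b268
21,Warm temperate moist forest,warm_temperate,frost,4.5,2.5,7,Temperate forest,#66b268
22,Warm temperate wet forest,warm_temperate,frost,5.5,1.5,7,Temperate forest,#66b268
23,Warm temperate rain forest,warm_temperate,frost,6.5,0.5,7,Temperate forest,#66b268
24,Subtropical desert,warm_temperate,frost_free,0.5,6.5,8,Subtropical desert,#f0b27a
25,Subtropical desert scrub,warm_temperate,frost_free,1.5,5.5,8,Subtropical desert,#f0b27a
26,Subtropical thorn woodland,warm_temperate,frost_free,2.5,4.5,9,Subtropical dry forest,#b7d078
27,Subtropical dry forest,warm_temperate,frost_free,3.5,3.5,9,Subtropical dry forest,#b7d078
28,Subtropical moist forest,warm_temperate,frost_free,4.5,2.5,10,Subtropical forest,#3fa34d
29,Subtropical wet forest,warm_temperate,frost_free,5.5,1.5,10,Subtropical forest,#3fa34d
30,Subtropical rain forest,warm_temperate,frost_free,6.5,0.5,10,Subtropical forest,#3fa34d
31,Tropical desert,tropical,any,0.5,7.5,11,Tropical desert,#e67e22
32,Tropical desert scrub,tropical,any,1.5,6.5,11,Tropical desert,#e67e22
33,Tropical thorn woodland,tropical,any,2.5,5.5,12,Tropical dry forest,#a9c937
34,Tropical very dry forest,tropical,any,3.5,4.5,12,Tropical dry forest,#a9c937
35,Tropical dry forest,tropical,any,4.5,3.5,12,Tropical dry forest,#a9c937
36,Tropical moist forest,tropical,any,5.5,2.5,13,Tropical forest,#1e8449
37,Tropical wet forest,tropical,any,6.5,1.5,13,Tropical forest,#1e8449
38,Tropical rain forest,tropical,any,7.5,0.5,13,Tropical forest,#1e8449
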