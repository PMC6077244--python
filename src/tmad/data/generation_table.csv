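# Rescaled Weibel symmetric lung morphometry (total airspace 3,700 ml).
# generation: Weibel generation index (0 = trachea, 23 = alveolar sacs)
# position_cm: cumulative axial position of the generation end, mouth = 0
# area_cm2: total airway (duct) cross-sectional area of the generation
# alveoli_fraction: fraction of the total alveoli in the generation
#   (non-zero for generations 17-23 only; sums to 1)
# Generations 18-23 areas and all alveoli fractions are approximations of
# the rescaled distribution; edit this file to supply better morphometry.
generation,position_cm,area_cm2,alveoli_fraction
0,11.979734,0.337223,0.000000
1,16.731695,0.712869,0.000000
2,18.628486,1.063279,0.000000
3,19.387202,1.279820,0.000000
4,20.655057,1.823688,0.000000
5,21.723250,2.604452,0.000000
6,22.621730,3.727001,0.000000
7,23.380447,5.354724,0.000000
8,24.019366,7.722088,0.000000
9,24.558454,11.195559,0.000000
10,25.017677,16.403032,0.000000
11,25.407018,24.300235,0.000000
12,25.736461,36.471495,0.000000
13,26.006005,54.797044,0.000000
14,26.235616,83.996780,0.000000
15,26.435279,133.584423,0.000000
16,26.600000,217.000000,0.000000
17,26.685714,217.000000,0.013659
18,26.771429,393.000000,0.023220
19,26.857143,707.000000,0.039474
20,26.942857,1261.000000,0.067106
21,27.028571,2213.000000,0.114080
22,27.114286,3857.000000,0.193919
23,27.200000,8535.000000,0.548542
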