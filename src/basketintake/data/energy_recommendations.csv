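age_min,age_max,female_kcal,male_kcal
0,1,625,695
2,3,1165,1230
4,6,1482,1577
7,10,1740,1969
11,14,2103,2220
15,18,2110,2755
19,49,1928,2532
50,64,1900,2380
65,74,1912,2342
75,120,1840,2294
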