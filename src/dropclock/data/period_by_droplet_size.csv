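a,mean_period_primary,var_period_primary,mean_period_secondary,var_period_secondary
1,16.357,57.06,9.077,56.095
2,16.608,52.225,9.3168,53.431
3,16.18,53.93,9.3788,52.724
4,16.426,53.351,10.025,52.699
5,17.068,50.007,10.468,52.338
6,16.504,49.729,10.267,49.443
7,16.324,47.549,10.115,47.244
8,16.23,51.906,9.708,47.59
9,16.537,51.911,10.065,49.642
10,16.701,50.377,10.539,47.125
11,16.206,55.129,10.424,48.35
12,17.034,41.147,10.86,44.434
13,16.388,46.923,10.171,47.247
14,16.768,45.904,10.725,46.066
15,17.214,42.897,11.502,42.188
16,17.146,46.499,10.893,53.131
17,17.445,37.217,11.106,42.044
18,16.879,53.687,9.6857,52.153
19,16.853,49.419,10.92,40.386
20,16.129,39.879,10.628,24.815
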