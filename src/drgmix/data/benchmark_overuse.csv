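group_id,n_total,n_normal,n_overuse,overuse_rate,mean_normal,mean_overuse,times,los_median_normal,los_median_overuse,cc_mean_normal,cc_mean_overuse
1,8124,7908,216,2.66,402.93,1687.42,4.19,10,20,5,6
2,16678,16192,486,2.91,1082.84,3246.01,3.00,12,25,5,6
3,23599,21883,1716,7.27,1700.59,5942.31,3.49,12,28,5,5
4,6806,6424,382,5.61,322.34,999.85,3.10,8,16,3,4
5,9034,8649,385,4.26,859.32,2627.81,3.06,10,24,4,6
6,11421,10670,751,6.58,1318.31,4725.59,3.58,10,21,4,5
7,1181,1108,73,6.18,735.50,2235.95,3.04,12,27,6,7
8,4171,3852,319,7.65,1272.48,4921.30,3.87,14,28,6,7
9,6947,6173,774,11.14,2153.25,8872.48,4.12,13,30,6,7
10,595,551,44,7.39,397.63,1562.86,3.93,9,23,4,7
11,1974,1836,138,6.99,969.08,3374.85,3.48,9,22,6,7
12,3601,3206,395,10.97,1627.37,6475.59,3.98,10,23,6,7
13,1499,1391,108,7.20,374.26,1186.68,3.17,10,19,1,2
14,2113,2006,107,5.06,839.79,2660.06,3.17,10,19,2,0
15,4186,3869,317,7.57,1493.79,5459.46,3.65,10,19,1,0
16,3258,3050,208,6.38,254.29,784.02,3.08,8,19,0,0
17,1801,1719,82,4.55,687.13,2210.65,3.22,8,17,0,1
18,2326,2166,160,6.88,1122.33,3637.13,3.24,8,15,1,0
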