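group_id,n,mean,sd,cv,iqr,p75,weight,upper_limit
1,8124,690.06,429.50,0.62,408.76,878.74,0.44,1491.88
2,16678,1221.77,696.15,0.57,812.78,1475.49,0.78,2694.67
3,23599,2254.00,1765.26,0.78,1226.55,2682.47,1.44,4522.30
4,6806,393.12,260.54,0.66,221.21,495.97,0.25,827.80
5,9034,1016.63,635.00,0.62,626.96,1244.75,0.65,2185.20
6,11421,1722.86,1414.44,0.82,950.34,2051.82,1.10,3477.33
7,1181,897.35,702.25,0.78,508.78,1097.60,0.57,1860.78
8,4171,1716.34,1556.73,0.91,951.45,1910.65,1.10,3337.84
9,6947,3321.90,2987.84,0.90,1509.59,3979.61,2.12,6244.00
10,595,509.94,387.42,0.76,265.23,624.46,0.33,1022.32
11,1974,1287.61,1159.70,0.90,698.37,1477.42,0.82,2524.98
12,3601,2464.50,2390.28,0.97,1150.48,2825.83,1.58,4551.56
13,1499,483.94,384.73,0.79,239.80,619.81,0.31,979.52
14,2113,999.32,683.14,0.68,601.24,1195.92,0.64,2097.78
15,4186,2012.63,1859.25,0.92,1028.90,2340.47,1.29,3883.82
16,3258,319.17,223.00,0.70,164.41,423.00,0.20,669.62
17,1801,827.55,605.01,0.73,489.66,1025.23,0.53,1759.72
18,2326,1498.25,1422.46,0.95,766.26,1782.33,0.96,2931.73
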