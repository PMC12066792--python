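group_id,n_total,n_normal,n_overuse,overuse_rate,mean_normal,mean_overuse,times,los_median_normal,los_median_overuse,cc_mean_normal,cc_mean_overuse
1,28643,26456,2187,7.64,482.91,1573.29,3.26,10,19,3,6
2,50725,47623,3093,6.10,1129.17,3777.58,3.35,10,24,5,6
3,23535,21749,1786,7.59,1907.56,6823.83,3.58,12,27,5,6
4,6411,5729,682,10.64,2354.15,9349.16,3.97,13,28,5,7
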