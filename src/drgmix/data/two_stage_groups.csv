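group_id,n,mean,sd,cv,iqr,p75,weight,upper_limit
1,28643,625.10,492.09,0.79,301.84,820.48,0.52,1273.24
2,50725,1412.13,1118.14,0.79,820.11,1643.08,1.05,2873.25
3,23535,2521.85,1882.56,0.75,1403.93,2911.92,1.86,5017.82
4,6411,3443.37,2504.83,0.73,1683.88,4025.18,2.57,6551.00
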