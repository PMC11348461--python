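compound_id,block,X,R1,R2,R3,R4,Y,Z,R5,R6,inhibition_pct,inhibition_pct_printed,inhibition_sd,hm_predicted,target_log,gep_model,is_test,printed_target_hm,printed_difference,printed_target_gep,printed_residual
1,1,O,Ph,,,,,,,,68.4,68.4,2.9,1.725,1.835,1.964,1,1.835,-0.11,1.835,0.129
2,1,CH2,Ph,,,,,,,,90.3,90.3,0.9,1.763,1.956,1.824,0,1.956,-0.192,1.956,0.131
3,1,CH2,4-F-phenyl,,,,,,,,33.6,33.6,1.3,1.77,1.526,1.666,0,1.526,0.243,1.526,0.14
4,1,CH2,3-F-phenyl,,,,,,,,56.8,56.8,0.7,1.765,1.754,1.749,0,1.754,0.011,1.754,5.461
5,1,CH2,4-OMe-phenyl,,,,,,,,16.9,16.9,0.1,1.571,1.228,1.097,1,1.228,0.343,1.228,0.13
6,1,CH2,3-OMe-phenyl,,,,,,,,47.1,41.7,0.6,1.648,1.673,1.91,0,1.673,-0.025,1.673,0.237
7,1,CH2,4-Cl-phenyl,,,,,,,,89.0,89.0,1.5,1.77,1.949,1.951,0,1.949,-0.179,1.949,1.251
8,1,CH2,3-Cl-phenyl,,,,,,,,69.5,69.5,3.2,1.762,1.842,1.856,1,1.842,-0.08,1.842,1.352
9,1,CH2,4-pyridyl,,,,,,,,41.4,41.4,1.0,1.705,1.617,1.653,0,1.617,0.088,1.617,0.036
10,1,CH2,3-pyridy,,,,,,,,66.5,66.5,1.1,1.713,1.823,1.718,1,1.823,-0.11,1.823,0.105
11,1,CH2,3-thienyl,,,,,,,,52.2,52.2,1.2,1.766,1.718,1.85,0,1.718,0.048,1.718,0.133
12,1,CH2,2-thienyl,,,,,,,,65.4,65.4,1.0,1.763,1.816,1.775,1,1.816,-0.053,1.816,4.1
13,1,CH2,2-thiazolyl,,,,,,,,86.3,86.3,2.2,1.678,1.936,1.813,0,1.936,-0.258,1.936,0.123
14,1,CH2,cyclohexyl,,,,,,,,35.4,35.4,0.6,1.579,1.549,1.679,0,1.549,0.03,1.549,0.13
15,1,CH2,cyclopentyl,,,,,,,,14.0,14.0,0.8,1.567,1.146,1.203,0,1.146,0.421,1.146,5.688
16,1,CH2,cyclopropyl,,,,,,,,57.4,57.4,1.1,1.602,1.759,1.859,1,1.759,-0.157,1.759,0.1
b2,2,,,Me,Me,H,,,,,90.3,90.3,0.9,1.766,1.956,1.98,0,1.956,-0.19,1.956,2.474
17,2,,,Me,H,H,,,,,74.2,74.2,6.5,1.889,1.87,1.746,0,1.87,0.019,1.87,0.124
18,2,,,F,H,H,,,,,74.0,74.0,5.6,1.923,1.869,1.971,1,1.869,0.054,1.869,0.102
19,2,,,H,H,H,,,,,55.3,55.3,1.8,1.926,1.743,1.844,0,1.743,0.183,1.743,0.102
20,2,,,H,H,Me,,,,,69.9,69.9,5.4,1.877,1.844,1.773,0,1.845,0.033,1.771,2.267
21,2,,,H,H,OMe,,,,,59.0,59.0,1.4,1.683,1.771,1.854,0,1.771,-0.088,1.849,4.817
22,2,,,H,H,NMe2,,,,,70.6,70.6,1.9,1.823,1.849,1.814,0,1.849,-0.026,1.812,2.266
23,2,,,H,H,4-morpholinyl,,,,,64.8,64.8,5.5,1.726,1.812,1.843,0,1.812,-0.085,1.847,4.358
24,2,,,H,H,F,,,,,70.3,70.3,5.7,1.915,1.847,1.744,0,1.847,0.068,1.857,0.113
25,2,,,H,H,CF3,,,,,72.0,72.0,3.7,1.875,1.857,1.678,1,1.857,0.018,1.844,0.166
26,2,,,H,H,SO2CH3,,,,,69.9,69.9,4.1,1.795,1.844,1.809,0,1.845,-0.05,1.844,3.516
b3,3,,,,,,C(=O),C(=O),H,H,90.3,90.3,0.9,2.002,1.956,1.815,0,1.956,0.046,1.956,0.141
27,3,,,,,,C(=O),C(=O),F,H,83.9,83.9,2.4,1.98,1.924,1.891,0,1.924,0.056,1.924,3.248
28,3,,,,,,C(=O),C(=O),OMe,H,84.4,84.4,1.6,1.811,1.926,1.868,0,1.926,0.116,1.926,5.844
29,3,,,,,,C(=O),C(=O),H,H,89.4,89.4,1.3,1.966,1.951,1.77,1,1.951,0.014,1.951,0.181
30,3,,,,,,C(=O),C(=O),H,H,52.1,52.1,1.2,1.89,1.717,1.685,0,1.717,0.173,1.717,3.182
31,3,,,,,,C(=O),C(=O),H,H,79.3,79.3,0.7,1.916,1.899,1.908,0,1.899,0.016,1.899,8.996
32,3,,,,,,C(=O),C(=O),H,H,82.0,82.0,3.7,1.869,1.914,1.908,0,1.914,-0.045,1.914,5.725
33,3,,,,,,CH2,C(=O),H,H,76.5,76.5,5.6,1.911,1.884,1.799,0,1.884,0.028,1.884,8.514
34,3,,,,,,CH2,C(=O),H,H,92.9,92.9,1.9,1.985,1.968,1.954,0,1.968,0.017,1.968,1.367
35,3,,,,,,CH2,C(=O),H,H,83.3,83.3,1.6,1.883,1.921,1.966,0,1.921,-0.037,1.921,4.583
36,3,,,,,,CH2,C(=O),H,H,87.2,87.2,0.5,1.833,1.941,1.926,0,1.941,-0.108,1.941,1.487
37,3,,,,,,C(=O),H,H,H,23.1,23.1,1.8,1.364,1.364,1.481,0,1.364,0.0,1.363,0.117
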