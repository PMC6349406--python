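neuron,sites,branches,mean_erev_mV,sd_mV,cv,is_group_mean
PD,30,6,-64.70,3.80,0.06,0
PD,23,4,-66.30,3.20,0.05,0
PD,10,3,-74.30,3.00,0.04,0
PD,23,4,-64.18,4.05,0.06,0
PD,20,4,-69.56,4.35,0.06,0
PD,23,4,-83.00,6.22,0.08,0
PD_MEAN,21.5,4.2,-70.34,4.10,0.06,1
LP,11,2,-65.72,6.18,0.09,0
LP,26,5,-72.82,2.33,0.03,0
LP,25,5,-71.87,3.89,0.05,0
LP,25,5,-81.67,4.07,0.05,0
LP,24,5,-71.87,3.89,0.05,0
LP_MEAN,22.2,4.4,-72.79,4.07,0.05,1
VD,27,4,-76.22,3.75,0.05,0
VD,19,4,-80.83,6.14,0.08,0
VD,24,4,-83.86,6.75,0.08,0
VD,15,4,-74.81,4.29,0.06,0
VD,15,5,-77.84,8.23,0.11,0
VD_MEAN,20,4.2,-78.71,5.83,0.08,1
GM,10,2,-62.33,0.80,0.01,0
GM,28,5,-74.00,1.55,0.02,0
GM,25,6,-74.78,2.43,0.03,0
GM,20,5,-75.42,3.57,0.05,0
GM,19,4,-65.66,7.05,0.11,0
GM_MEAN,20.4,4.4,-70.44,3.08,0.04,1
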