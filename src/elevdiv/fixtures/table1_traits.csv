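sonotype,FA,AR,WL,I,fmaxe,pfc.min,pfc.max,Duration
AMN,39.06,7.77,11.86,0.93,35.56,31.31,67.65,7.13
Bdar,39.49,5.72,8.55,0.7,34.83,24.74,41.34,5
EH,49.52,7.14,9.48,1.17,29.19,22.81,47.57,8.02
Mful,49.15,6.89,9.4,0.82,49.31,48.09,86.91,7
Mmur,36.38,6.79,5.43,1.19,53.06,46.32,96.19,3.92
MP,34.71,7.03,6.84,1.1,40.03,36.98,70.39,5.69
MS,34.85,6.95,5.84,1.34,62.93,57.6,102.08,4.27
Murina,30.29,6.22,6.51,1.5,83.2,70.8,122.24,2.62
Plecotus,40.03,6.6,6.1,1.68,36.72,28.95,43.85,2.7
Rlep,37.47,6.78,6.51,2.52,97.93,81.93,98.72,7.3
Rluc,71.06,6.29,11.26,2.35,31.25,27.78,31.25,49.46
Rpea,53.77,6.12,8.27,2.2,59.51,50.5,59.81,31.68
Rsin,48.81,6.14,10.87,1.79,84.06,73.7,84.34,32.4
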