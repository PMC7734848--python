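subject_id,group,ifng_blood,il17_blood,il10_blood,ifng_csf,il17_csf,il10_csf
MS1,MS,169.22,30.83,3.52,13.24,3.31,0.06
MS2,MS,21.56,5.33,1.02,5.59,1.71,0.06
MS3,MS,71.10,15.45,2.46,16.10,0.60,0.10
MS4,MS,15.44,21.34,1.54,3.36,0.88,0.04
MS5,MS,148.65,28.66,2.27,17.80,2.87,0.10
MS6,MS,60.31,15.80,4.38,12.27,1.18,0.14
MS7,MS,377.13,53.86,5.13,29.64,2.29,0.11
MS8,MS,156.74,21.87,8.26,10.15,1.64,0.13
HD1,HD,42.37,21.19,26.98,0.30,0.30,0.40
HD2,HD,2.40,13.20,16.80,0.80,0.20,1.00
HD3,HD,8.70,7.83,8.18,0.20,0.80,1.00
HD4,HD,69.30,3.15,11.76,1.00,1.00,1.00
HD5,HD,16.15,2.38,8.27,0.10,0.80,0.10
HD6,HD,18.45,1.64,6.48,2.00,1.00,2.00
HD7,HD,63.00,7.88,10.94,0.10,0.10,0.80
HD8,HD,97.27,13.70,12.06,0.20,1.90,1.90
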