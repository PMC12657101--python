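whale_id,location,n_subglides,rho_t,rho_t_cri,n_images,length_m,length_ci,volume_m3,volume_ci,dpl_pct,dpl_cri,lipid_t,lipid_cri,spermaceti_t
sw19_250ab,Norway,118,1029.9,0.07,1,15.21,,50.06,,-0.4,0.46,10.1,2.13,2.29
sw19_253abc,Norway,85,1029.32,0.07,6,13.91,0.83,32.97,4.48,-0.12,0.45,7.55,0.94,1.63
sw21_196a,Azores,79,1027.1,0.18,3,8.41,0.07,8.97,0.45,0.94,0.48,2.06,0.22,0.36
sw21_211a,Azores,41,1030.77,0.17,5,9.71,0.41,11.67,2.19,-0.81,0.48,2.57,0.34,0.55
sw21_215a,Azores,80,1027.81,0.15,2,9.92,0.21,13.2,1.41,0.59,0.45,3.12,0.49,0.58
sw21_221a,Azores,56,1028.59,0.08,4,9.78,0.28,16.43,1.45,0.23,0.46,3.29,0.85,0.64
sw21_230a,Azores,126,1027.33,0.08,2,9.48,0.03,13.9,1.74,0.83,0.45,2.98,0.53,0.54
sw21_230b,Azores,58,1027.21,0.11,0,,,,,0.88,0.45,,,
sw21_232a,Azores,,,,3,9.57,0.06,13.31,1.57,0.54,2.37,2.91,0.63,0.54
sw21_232b,Azores,38,1024.29,0.1,0,,,,,2.29,0.45,,,
sw21_242a,Azores,34,1025.44,0.23,2,8.42,0.13,9.53,0.82,1.73,0.5,2.24,0.37,0.36
sw22_181a,Azores,114,1029.0,0.06,0,,,,,0.03,0.45,,,
sw22_192a,Azores,37,1031.9,0.12,3,10.72,0.81,15.24,2.81,-1.35,0.46,3.25,0.55,0.75
sw22_201a,Azores,25,1027.22,0.14,4,8.72,0.65,8.75,2.69,0.88,0.46,2.14,0.43,0.38
sw22_201b,Azores,85,1028.2,0.09,3,8.28,0.55,10.03,1.86,0.42,0.46,2.09,0.51,0.38
sw22_209a,Azores,17,,,4,10.31,0.39,15.04,1.15,-0.08,2.21,3.34,0.59,0.67
sw22_210a,Azores,39,1026.67,0.13,3,13.05,0.41,33.3,1.6,1.14,0.45,7.54,0.92,1.42
sw22_216a,Azores,31,1027.76,0.11,3,9.21,0.14,9.6,0.46,0.62,0.46,2.4,0.55,0.44
sw22_223a,Azores,70,1028.76,0.08,4,9.6,0.23,13.33,1.48,0.15,0.46,2.86,0.34,0.56
sw22_224a,Azores,,,,3,10.8,0.31,17.37,0.61,0.02,2.34,3.86,0.71,0.78
sw22_229a,Azores,26,1028.63,0.15,1,9.58,,12.69,,0.21,0.46,2.81,0.63,0.54
sw22_234a,Azores,25,1026.19,0.25,1,10.21,,15.74,,1.37,0.5,3.72,0.85,0.65
sw22_234b,Azores,,,,2,9.9,0.61,11.86,2.39,-0.44,2.84,2.73,0.83,0.56
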