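pattern,ctl_mean_mM,ctl_disp,ko_mean_mM,ko_disp,p_reported,pct_change_reported
"[4-13C]Glu",1.489,0.17,1.940,0.09,0.007,30.289
"[3-13C]Glu",1.147,0.07,1.381,0.05,0.009,20.401
"[2-13C]Glu",1.128,0.09,1.384,0.012,0.042,22.695
"[1-13C]Glu",0.630,0.04,0.717,0.01,0.010,13.810
"[4,5-13C]Glu",0.427,0.04,0.517,0.03,0.118,21.077
"[2,3-13C]Glu",0.525,0.08,0.839,0.07,0.003,59.810
"[3,4-13C]Glu",0.784,0.13,1.073,0.105,0.028,36.862
"[1,2-13C]Glu",0.378,0.06,0.507,0.08,0.065,34.127
"[4-13C]Gln",0.506,0.07,0.550,0.008,0.307,8.696
"[3-13C]Gln",0.521,0.05,0.594,0.01,0.057,14.012
"[2-13C]Gln",0.503,0.02,0.597,0.04,0.010,18.688
"[1-13C]Gln",0.338,0.04,0.384,0.02,0.116,13.609
"[4,5-13C]Gln",0.339,0.07,0.380,0.06,0.382,12.094
"[2,3-13C]Gln",0.220,0.04,0.278,0.03,0.077,36.364
"[3,4-13C]Gln",0.210,0.25,0.445,0.008,0.166,111.905
"[1,2-13C]Gln",0.222,0.05,0.258,0.07,0.430,16.216
"[4-13C]Asp",0.296,0.07,0.298,0.03,0.960,0.676
"[3-13C]Asp",0.403,0.03,0.433,0.02,0.212,7.444
"[2-13C]Asp",0.283,0.02,0.315,0.01,0.058,11.307
"[1-13C]Asp",0.281,0.09,0.236,0.04,0.470,-16.014
"[3,4-13C]Asp",0.110,0.03,0.113,0.04,0.879,2.727
"[2,3-13C]Asp",0.157,0.03,0.204,0.06,0.527,29.936
"[1,2-13C]Asp",0.064,0.02,0.111,0.002,0.020,73.438
"[3-13C]NAA",0.123,0.02,0.132,0.06,0.764,7.317
"[2-13C]NAA",0.082,0.02,0.089,0.001,0.614,11.307
"[6-13C]NAA",0.115,0.02,0.111,0.02,0.813,-3.478
"[4-13C]GABA",0.280,0.03,0.342,0.08,0.192,22.143
"[3-13C]GABA",0.347,0.02,0.370,0.06,0.470,6.628
"[2-13C]GABA",0.337,0.04,0.380,0.03,0.209,12.760
"[1-13C]GABA",0.209,0.03,0.342,0.08,0.821,63.636
"[3,4-13C]GABA",0.280,0.001,0.040,0.02,0.195,-85.714
"[2,3-13C]GABA",0.132,0.008,0.118,0.04,0.522,-10.606
"[1,2-13C]GABA",0.099,0.04,0.095,0.08,0.931,-4.040
"[4,6-13C]MI",0.097,0.006,0.117,0.02,0.098,20.619
"[2-13C]MI",0.040,0.01,0.035,0.001,0.567,-12.500
"[1,3-13C]MI",0.105,0.02,0.117,0.02,0.493,11.429
"[5-13C]MI",0.056,0.02,0.070,0.001,0.416,25.000
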