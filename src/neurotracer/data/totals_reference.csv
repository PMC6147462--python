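metabolite,ctl_mean_mM,ctl_sd,ko_mean_mM,ko_sd,p_reported
Asp,2.72,0.54,2.23,0.29,0.11
Glu,12.21,1.55,10.39,1.44,0.14
Gln,4.99,0.20,4.38,0.65,0.08
GABA,2.74,0.16,2.48,0.39,0.22
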