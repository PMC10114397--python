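subject_id,phase,va_logmar,brbp_right,brbp_left,pep_h_deg,stereo_arcsec
S1,pre,1.00,,4,1.2,400
S1,post,0.10,8,7,0.64,200
S2,pre,0.60,7,3,1.5,none
S2,post,0.10,8,6,0.18,400
S3,pre,0.60,2,8,0.5,none
S3,post,0.10,6,8,0.32,none
S4,pre,0.80,8,1,0.58,none
S4,post,0.20,8,6,0.36,none
S5,pre,0.80,6,5,0.48,none
S5,post,0.10,8,6,0.38,none
S6,pre,0.20,5,8,0.42,none
S6,post,0.10,7,8,0.14,none
S7,pre,0.50,3,4,1.46,100
S7,post,0.15,8,6,0.8,100
S8,pre,0.40,4,8,0.28,none
S8,post,0.10,6,8,0.1,none
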