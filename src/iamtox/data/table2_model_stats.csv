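endpoint_id,descriptor,equation,r,r2,r2_adj,s,f
fish_pLC50,chi_iam,1,0.924,0.854,0.848,0.384,157
fish_pLC50,log_p,2,0.858,0.735,0.715,0.527,36.1
daphnia_pEC50,chi_iam,3,0.907,0.823,0.817,0.335,125
daphnia_pEC50,log_p,4,0.816,0.665,0.639,0.471,25.8
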