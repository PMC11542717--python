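metric,logp_model,chi_model,external_tool
rmsep,0.55,0.42,1.16
rsep_percent,13.8,10.4,28.9
bias,0.09,0.18,0.54
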