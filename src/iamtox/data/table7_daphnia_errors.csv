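metric,logp_model,chi_model,external_tool
rmsep,0.65,0.45,0.88
rsep_percent,14.5,10.1,19.8
bias,-0.46,-0.17,0.42
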