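name,p_value,conc_mg_l,hazard_ranking
Homosalate,4.85,3.71,Acute toxicity II / Toxic
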