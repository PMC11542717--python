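name,p_value,conc_mg_l,hazard_ranking
Avobenzone,4.97,3.35,Acute toxicity II / Toxic
Dioxybenzone,4.32,11.7,Acute toxicity III / Harmful
Homosalate,5.13,1.93,Acute toxicity II / Toxic
Octinoxate,5.00,2.84,Acute toxicity II / Toxic
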