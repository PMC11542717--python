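name,experimental,chi_model,logp_model,external_tool,resid_chi,resid_logp,resid_epi
4-Aminobenzoic Acid,2.12,2.56,2.45,2.12,0.44,0.33,0.00
Ensulizole,2.91,3.04,2.24,2.05,0.13,0.67,0.86
Meradimate,4.48,5.14,4.92,6.37,0.66,0.44,1.89
Octisalate,4.40,5.05,5.11,6.19,0.65,0.71,1.79
Octocrylene,5.65,5.29,6.02,6.73,0.72,0.37,1.08
Oxybenzone,4.78,4.36,4.14,4.92,0.42,0.64,0.14
Padimate O,4.85,4.98,5.20,6.07,0.16,0.35,1.22
Sulisobenzone,2.69,3.09,2.22,1.52,0.40,0.47,1.17
Trolamine salicylate (Salicylic acid),2.00,2.46,1.69,3.26,0.46,0.31,1.26
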