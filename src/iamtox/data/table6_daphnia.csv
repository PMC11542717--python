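name,experimental,chi_model,logp_model,external_tool,resid_chi,resid_logp,resid_epi
4-Aminobenzoic Acid,3.26,2.82,2.74,4.14,0.44,0.52,0.88
Avobenzone,5.20,4.72,4.53,5.64,0.48,0.67,0.44
Dioxybenzone,4.76,4.21,3.98,4.78,0.55,0.78,0.02
Ensulizole,3.44,3.19,2.58,3.04,0.25,0.86,0.40
Meradimate,5.24,4.86,4.62,6.25,0.38,0.62,1.01
Octinoxate,5.03,4.75,4.95,5.95,0.28,0.08,0.92
Octisalate,5.58,4.79,4.76,6.06,0.79,0.82,0.48
Octocrylene,5.06,4.97,5.43,6.63,0.09,0.37,1.57
Oxybenzone,4.92,4.24,4.23,5.15,0.68,0.69,0.23
Padimate O,4.69,4.73,4.82,5.93,0.04,0.13,1.24
Sulisobenzone,3.79,3.23,2.57,2.36,0.56,1.22,1.43
Trolamine salicylate (Salicylic acid),2.67,2.73,2.17,2.74,0.06,0.50,0.07
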