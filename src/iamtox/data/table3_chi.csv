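name,chi_iam
4-Aminobenzoic Acid,3.30
Avobenzone,53.4
Dioxybenzone,39.9
Ensulizole,13.2
Homosalate,56.8
Meradimate,56.9
Octinoxate,54.2
Octisalate,55.1
Octocrylene,60.0
Oxybenzone,40.8
Padimate O,53.6
Sulisobenzone,14.3
Trolamine salicylate (Salicylic acid),1.13
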