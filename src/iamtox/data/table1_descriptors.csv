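name,log_p,log_d74,mw,tpsa,f_minus,f_plus,f_zwit,abraham_a,abraham_b,hbd,hba
4-Aminobenzoic Acid,0.83,-1.60,137,63.2,1.00,0.00,0.00,0.94,0.60,3,3
Avobenzone,4.58,4.53,310,43.4,0.10,0.00,0.00,0.00,1.08,0,3
Dioxybenzone,2.99,2.89,244,66.8,0.18,0.00,0.00,0.41,0.70,2,4
Ensulizole,0.31,-3.73,274,91.4,1.00,0.00,0.00,0.66,1.43,2,5
Homosalate,4.90,4.90,262,46.5,0.00,0.00,0.00,0.13,0.49,1,3
Meradimate,4.64,4.64,275,52.3,0.00,0.00,0.00,0.18,0.83,2,3
Octinoxate,5.71,5.71,290,35.5,0.00,0.00,0.00,0.00,0.78,0,3
Octisalate,5.10,5.10,250,46.5,0.00,0.00,0.00,0.13,0.45,1,3
Octocrylene,7.27,7.27,361,50.1,0.00,0.00,0.00,0.00,0.86,0,3
Oxybenzone,3.50,2.89,228,46.5,0.18,0.00,0.00,0.13,0.62,1,3
Padimate O,5.31,5.31,277,29.5,0.00,0.00,0.00,0.00,0.84,0,3
Trolamine salicylate (Salicylic acid),2.04,-1.89,138,57.3,1.00,0.00,0.00,0.71,0.38,2,3
Sulisobenzone,0.28,-4.71,308,109,1.00,0.00,0.00,0.45,1.37,2,6
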