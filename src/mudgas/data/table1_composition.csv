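sample,ch4,co2,c2h6,c3h8,i_c4h10,n_c4h10
G-1,96.66,2.18,0.74,0.10,0.26,0.05
G-2,96.74,2.07,0.76,0.11,0.28,0.05
M-1,93.19,5.95,0.67,0.20,bdl,bdl
M-2,94.39,4.70,0.59,0.32,bdl,bdl
M-3,93.94,6.02,0.03,0.002,bdl,bdl
M-4,96.50,3.43,0.05,0.02,bdl,bdl
M-5,95.38,4.41,0.13,0.07,bdl,bdl
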