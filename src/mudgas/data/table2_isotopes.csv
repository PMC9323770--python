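sample,d13c_ch4,dd_ch4,d13c_co2,d13c_c2h6,d13c_c3h8,d13c_i_c4h10,d13c_n_c4h10,delta13c_central,d13c_central,d13c_terminal
G-1,-34.1,-170,28.5,-21.2,-9.8,-24.3,-14.6,31.5,11.2,-20.3
G-2,-34.9,-167,24.4,-21.6,-10.2,-25.2,-15.3,30.5,10.1,-20.4
M-1,-37.2,-170,34.5,-26.0,-13.5,bdl,bdl,29.2,5.9,-23.3
M-2,-36.8,-170,34.1,-26.3,-14.4,bdl,bdl,28.3,4.4,-23.9
M-3,-37.0,-181,32.7,-23.3,-1.7,bdl,bdl,bdl,,
M-4,-38.6,-182,19.1,-24.9,-8.8,bdl,bdl,40.5,18.2,-22.3
M-5,-37.8,-175,33.8,-25.1,-10.4,bdl,bdl,37.2,14.4,-22.8
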