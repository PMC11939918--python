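figure,vesicle_diameter_nm,hydration_buffer,dilution_buffer,rinse_buffer,lipid_flow_start_min,lipid_flow_end_min,temperature_c
2A,118,B1,B1,B1,0,6.5,23
6A,80,B2,B2,B2,0,24,23
7A,81,B3,B3,B3,0,15,23
7C,108,B3,B3,B3,0,15,23
8A,114,B3,B3,B3,0,20,23
8C,114,B3,B3,B3,0,40,35
9A,58,B2,B4,B4,0,8,23
10A,55,B2,B4,B5,0,8,23
11A,65,B2,B5,B5,0,7,23
11C,81,B6,B2,B2,0,6.5,23
11D,74,B6,B2,B2,0,6,23
12A,80,B6,B2,B2,0,6,23
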