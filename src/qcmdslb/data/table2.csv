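figure,lipid,t_ads_min,dF_min_hz,dD_max_1e6,t_rup_min,dF_asymp_hz,dD_asymp_1e6,R_ads_hz_min,R_rup_hz_min,h_nm
2A,a,2.1,-56.5,2.2,1.4,-25.1,0.1,26.9,22.4,20.1
6A,f,23,-56.6,2.8,inf,-56.6,2.8,2.4,0,26.3
7A,f,9.1,-73.1,4.5,3.5,-67.3,7.8,8.0,1.7,30.3
7C,f,14.7,-94.4,17.2,inf,-94.4,17.2,6.4,0,45.2
8A,f,12.8,-110.5,16.9,6.0,-107.0,18.3,8.6,0.6,45.0
8C,f,4.9,-76.4,9.2,3.53,-64.1,8.9,15.6,3.6,41.7
9A,f,2.7,-79.8,3.0,2.88,-42.8,2.4,30.0,12.8,25.2
10A,f,2.7,-81.2,3.0,5.5,-45.8,3.0,30.2,6.4,24.2
11A,f,1.6,-45.1,1.9,1.95,-31.0,0.5,28.1,7.2,19.9
11C,f,1.4,-47.2,2.0,1.7,-30.6,0.5,34.4,9.8,19.4
11D,f,1.6,-42.1,1.7,1.5,-27.9,0.3,26.6,9.5,20.7
12Aa,a,2.2,-55.1,2.8,1.06,-24.8,0.1,25.4,28.6,19.5
12Ab,b,1.2,-48.1,2.9,1.0,-25.6,0.7,40.1,22.5,21.9
12Ac,c,0.6,-45.8,2.4,0.26,-25.2,0.1,81.7,79.1,19.6
12Ad,d,0.8,-59.0,3.6,0.48,-29.5,0.4,72.0,61.5,19.5
12Ae,e,1.0,-48.0,3.0,0.6,-25.6,0.2,46.1,37.3,22.6
12Af,f,1.9,-45.2,2.4,1.4,-30.2,0.2,24.4,10.7,19.6
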