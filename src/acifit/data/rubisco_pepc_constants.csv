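species,source,temperature_C,Kc_Pa,Kc_SE,Ko_kPa,Ko_SE,gammastar_Pa,gammastar_SE,Kp_Pa,Kp_SE
rice,own,25,29.1,1.6,45.7,4.6,4.19,0.19,,
rice,own,38,87.7,5.2,58.3,5.7,6.34,0.36,,
wheat,own,25,31.6,1.1,39.2,3.8,3.87,0.21,,
wheat,own,38,89.3,3.6,50.3,4.5,5.32,0.32,,
maize,own,25,85.8,7.0,39.8,3.5,4.30,0.30,8.0,3.0
maize,own,38,188.3,5.7,74.5,7.5,6.47,0.26,13.2,5.0
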