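species,growth_T_C,irrigation,meas_T_C,Vcmax_own,Vcmax_own_SE,Vpmax_own,Vpmax_own_SE,Vcmax_std,Vcmax_std_SE,Vpmax_std,Vpmax_std_SE
maize,25,WW,25,29.9,2.3,133.8,4.3,29.7,2.2,112.8,3.8
maize,25,WD,25,22.5,0.3,81.1,3.5,22.3,0.3,69.5,2.6
maize,25,WW,38,38.7,1.0,141.1,5.9,41.5,0.9,117.5,6.4
maize,25,WD,38,33.6,1.7,82.6,6.9,37.5,0.8,62.0,4.4
maize,38,WW,25,14.4,1.8,44.9,4.7,14.1,1.8,38.4,4.1
maize,38,WD,25,22.7,1.2,52.8,8.2,22.2,1.2,46.8,7.0
maize,38,WW,38,31.7,0.9,219.5,23.7,32.6,1.1,182.0,15.0
maize,38,WD,38,31.1,2.2,158.7,18.6,32.2,2.2,141.4,10.0
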