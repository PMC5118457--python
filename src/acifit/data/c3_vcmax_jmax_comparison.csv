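species,growth_T_C,irrigation,meas_T_C,Vcmax_own,Vcmax_own_SE,Jmax_own,Jmax_own_SE,Vcmax_std,Vcmax_std_SE,Jmax_std,Jmax_std_SE
rice,25,WW,25,102.7,6.1,184.5,9.2,116.0,6.0,112.7,22.3
rice,25,WD,25,70.1,6.2,146.7,13.2,77.9,7.2,82.8,4.5
rice,25,WW,38,185.1,10.8,208.3,5.9,206.2,10.8,197.6,6.9
rice,25,WD,38,182.2,5.0,207.3,4.2,195.8,3.1,198.5,0.3
rice,38,WW,25,70.2,5.4,118.8,6.6,78.0,5.8,108.8,5.1
rice,38,WD,25,50.2,3.3,90.0,1.6,59.2,3.8,79.3,2.7
rice,38,WW,38,222.1,11.0,215.4,12.6,228.3,14.4,198.5,11.0
rice,38,WD,38,173.2,6.8,173.4,11.8,176.5,15.2,161.4,5.8
wheat,25,WW,25,105.4,7.2,181.5,7.9,125.8,9.7,101.5,15.4
wheat,25,WD,25,122.9,2.1,199.8,7.1,144.1,3.3,81.9,2.5
wheat,25,WW,38,127.7,13.7,154.7,11.6,151.6,16.2,156.9,11.3
wheat,25,WD,38,119.2,3.3,125.3,5.4,134.5,8.9,119.7,5.8
wheat,38,WW,25,88.9,4.2,143.8,6.8,110.0,6.1,133.6,5.9
wheat,38,WD,25,80.9,5.9,127.2,5.7,104.5,6.1,122.8,6.6
wheat,38,WW,38,205.2,26.0,198.7,13.3,247.7,29.2,186.8,10.9
wheat,38,WD,38,197.8,13.5,181.1,7.6,230.3,15.9,174.2,8.6
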