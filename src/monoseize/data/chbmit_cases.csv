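case_id,age_yr,sex,n_seizures,seizure_length_mean_s,seizure_length_sd_s,total_seizure_length_s,recording_length_h,single_channel
chb01,11.0,F,7,50.6,23.0,354,40.6,P8-O2
chb02,11.0,M,3,50.7,36.3,152,35.3,P7-O1
chb03,14.0,F,7,39.3,6.0,275,38.0,Fp1-F3
chb04,22.0,M,4,32.8,16.3,131,156.1,P8-O2
chb05,7.0,F,5,71.4,16.1,357,39.0,P7-O1
chb07,14.5,F,3,37.0,7.5,111,67.1,Fp1-F3
chb08,3.5,M,5,42.4,20.4,212,20.0,Fp1-F3
chb10,3.0,M,7,44.1,14.6,309,50.0,P7-O1
chb11,12.0,F,3,46.7,46.2,140,34.8,P7-O1
chb15,16.0,M,20,80.8,46.5,1616,40.0,P7-O1
chb17,12.0,F,3,78.0,17.8,234,21.0,P8-O2
chb22,9.0,F,3,60.7,11.0,182,31.0,Fp1-F3
chb23,6.0,F,7,49.4,18.5,346,26.6,Fp1-F3
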