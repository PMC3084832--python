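stage,patient_id,age,sex,ethnicity,mean_fold,ci_low,ci_high,max_fold,pct_reactive
I,9,51,F,Caucasian,1.1,1,1,2.8,2
II,4,75,M,Caucasian,2.7,2.6,3,4.2,38
II,5,70,M,Caucasian,6.1,5.4,7,17,63
II,7,69,M,Caucasian,1.6,1.4,2,4.8,3
II,15,49,F,Caucasian,2.6,2.5,3,6.2,22
II,1,66,F,Caucasian,1.5,1.4,2,6.8,5
II,19,63,F,Caucasian,1.6,1.5,2,3.5,82
II,21,38,M,Caucasian,1.3,1.1,2,7.7,2
II,20,81,M,Caucasian,2,1.9,2,3.7,50
III,6,67,M,Caucasian,3.2,3,3,5.8,14
III,10,54,M,Caucasian,1.8,1.6,2,3.6,13
III,16,77,M,Caucasian,1.8,1.6,2,3.8,97
III,17,88,M,Caucasian,1.8,1.7,2,2.8,40
III,18,68,M,Caucasian,1.3,1.2,1,2.8,6
III,8,23,M,Asian,1,0.8,1,2.9,8
IV,11,77,F,Caucasian,1.7,1.5,2,3.3,92
IV,12,72,F,Caucasian,1,0.8,1,3.5,10
IV,2,66,M,Caucasian,1.8,1.7,2,3.1,19
IV,13,55,F,Caucasian,1.5,1.4,2,2.6,2
IV,3,51,M,Caucasian,1.8,1.7,2,2.7,8
IV,14,31,F,Caucasian,0.7,0.6,1,1.3,12
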