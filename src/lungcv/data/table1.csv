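subject,gender,age_years,height_cm,weight_kg,bmi,smoking_status,passive_smoker,allergy,allergy_airways,lung_function_abnormal,auc_gt_9p5,auc_gt_20
S1,M,49,191,82,22.5,never,no,yes,upper,no,76,29
S2,M,49,185,77,22.5,never,no,yes,upper,no,77,30
S3,M,50,190,85,23.5,never,no,yes,upper,no,78,30
S4,M,48,187,75,21.4,never,yes,no,,no,77,31
S5,M,50,178,72,22.7,never,no,no,,no,78,33
S6,M,69,181,100,30.5,never,yes,no,,no,78,34
S7,M,60,188,85,24.0,current,,no,,no,78,34
S8,F,65,177,66,21.1,current,,yes,lower,no,80,34
S9,F,51,170,85,29.4,never,yes,no,,no,78,36
S10,M,75,175,92,30.0,never,no,yes,upper,no,79,39
S11,M,73,175,77,24.9,ex-smoker,,no,,no,80,41
S12,F,67,172,78,26.4,never,yes,no,,no,83,47
S13,F,67,167,79,28.3,never,yes,yes,lower,no,84,47
P1,M,55,176,85,27.4,never,,,,yes,83,43
P2,M,81,167,58,20.8,ex-smoker,,,,yes,90,61
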