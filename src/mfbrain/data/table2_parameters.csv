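scheme,stage,feature,mean,sd
kaggle,no_dementia,D1,1.69,0.016
kaggle,no_dementia,D2,1.596,0.025
kaggle,no_dementia,alpha_max,2.318,0.055
kaggle,no_dementia,f_alpha_max,0.294,0.078
kaggle,no_dementia,alpha_min,1.65,0.028
kaggle,no_dementia,f_alpha_min,1.542,0.072
kaggle,no_dementia,width,0.67,0.062
kaggle,no_dementia,alpha0,1.69,0.016
kaggle,no_dementia,shift,0.289,0.027
kaggle,no_dementia,area,17.71,0.158
kaggle,very_mild,D1,1.62,0.021
kaggle,very_mild,D2,1.533,0.012
kaggle,very_mild,alpha_max,2.613,0.027
kaggle,very_mild,f_alpha_max,0.19697,0.018
kaggle,very_mild,alpha_min,1.64,0.03
kaggle,very_mild,f_alpha_min,1.481,0.027
kaggle,very_mild,width,0.796,0.042
kaggle,very_mild,alpha0,1.702,0.022
kaggle,very_mild,shift,0.341,0.032
kaggle,very_mild,area,15.46,0.151
kaggle,mild,D1,1.58,0.032
kaggle,mild,D2,1.463,0.032
kaggle,mild,alpha_max,2.635,0.063
kaggle,mild,f_alpha_max,0.224,0.042
kaggle,mild,alpha_min,1.634,0.034
kaggle,mild,f_alpha_min,1.383,0.097
kaggle,mild,width,0.974,0.079
kaggle,mild,alpha0,1.724,0.019
kaggle,mild,shift,0.401,0.035
kaggle,mild,area,13.47,0.148
kaggle,moderate,D1,1.453,0.018
kaggle,moderate,D2,1.402,0.028
kaggle,moderate,alpha_max,2.776,0.052
kaggle,moderate,f_alpha_max,0.122,0.014
kaggle,moderate,alpha_min,1.601,0.037
kaggle,moderate,f_alpha_min,1.37,0.082
kaggle,moderate,width,1.175,0.069
kaggle,moderate,alpha0,1.75,0.049
kaggle,moderate,shift,0.442,0.042
kaggle,moderate,area,11.31,0.207
adni,CN,D1,1.82,0.012
adni,CN,D2,1.74,0.025
adni,CN,alpha_max,2.42,0.032
adni,CN,f_alpha_max,0.634,0.011
adni,CN,alpha_min,1.53,0.022
adni,CN,f_alpha_min,1.21,0.021
adni,CN,width,0.935,0.071
adni,CN,alpha0,1.623,0.032
adni,CN,shift,0.211,0.041
adni,CN,area,18.63,0.132
adni,MCI,D1,1.76,0.021
adni,MCI,D2,1.65,0.011
adni,MCI,alpha_max,2.62,0.044
adni,MCI,f_alpha_max,0.435,0.063
adni,MCI,alpha_min,1.568,0.042
adni,MCI,f_alpha_min,1.335,0.066
adni,MCI,width,1.124,0.068
adni,MCI,alpha0,1.733,0.023
adni,MCI,shift,0.334,0.025
adni,MCI,area,16.32,0.169
adni,AD,D1,1.65,0.03
adni,AD,D2,1.54,0.024
adni,AD,alpha_max,2.83,0.036
adni,AD,f_alpha_max,0.235,0.034
adni,AD,alpha_min,1.635,0.027
adni,AD,f_alpha_min,1.46,0.036
adni,AD,width,1.436,0.056
adni,AD,alpha0,1.832,0.019
adni,AD,shift,0.452,0.015
adni,AD,area,14.58,0.201
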