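biomarker,original,mean,sd,min,max
T.gondii antibodies (IU/ml),0.220,0.562,0.444,0.326,2.388
Blood lead (ug/dL),1.482,1.658,0.066,1.537,1.753
"Mercury, total (ug/L)",1.958,1.847,0.110,1.628,2.049
"Mercury, inorganic (ug/L)",0.290,1.668,0.116,1.358,1.788
White blood cell count (1000 cells/uL),1.243,1.126,0.065,1.000,1.277
Lymphocyte percent (%),1.331,0.978,0.078,0.780,1.176
Monocyte percent (%),1.996,1.595,0.172,1.371,1.904
Segmented neutrophils percent (%),1.240,1.004,0.082,0.856,1.121
Eosinophils percent (%),1.770,0.971,0.126,0.819,1.406
Basophils percent (%),0.565,0.585,0.051,0.503,0.690
Lymphocyte number (1000 cells/uL),0.754,0.912,0.171,0.691,1.559
Monocyte number (1000 cells/uL),0.835,0.492,0.043,0.392,0.552
Segmented neutrophils num (1000 cell/uL),1.138,1.103,0.075,0.950,1.282
Eosinophils number (1000 cells/uL),0.229,0.129,0.026,0.052,0.157
Basophils number (1000 cells/uL),0.069,0.084,0.012,0.056,0.100
Red blood cell count (million cells/uL),0.829,1.083,0.148,0.898,1.595
Hemoglobin (g/dL),1.717,2.942,0.152,2.667,3.210
Hematocrit (%),0.847,2.798,0.148,2.533,3.103
Mean cell volume (fL),0.494,0.943,0.082,0.853,1.154
Mean cell hemoglobin (pg),0.848,1.307,0.045,1.251,1.432
Mean Cell hemoglobin concentration (MCHC) (g/dL),5.139,3.380,0.105,3.195,3.610
Red cell distribution width (%),3.423,1.918,0.105,1.685,2.058
Platelet count (1000 cells/uL),2.395,2.632,0.112,2.443,2.842
Mean platelet volume (fL),1.257,1.348,0.095,1.214,1.519
Blood cadmium (nmol/L),5.306,4.159,0.136,3.908,4.447
Glycohemoglobin (%),1.526,1.830,0.107,1.604,1.986
C-reactive protein (mg/dL),1.877,2.264,0.107,2.024,2.405
Direct HDL-Cholesterol (mg/dL),1.097,1.149,0.104,0.946,1.328
RBC folate (ng/mL),0.536,0.779,0.097,0.588,1.021
Serum folate (ng/mL),1.955,1.840,0.163,1.486,2.087
Cotinine (ng/mL),2.011,1.982,0.277,1.542,2.739
Urinary Total NNAL (ng/mL),3.226,5.579,0.496,4.544,6.459
Albumin (g/dL),0.914,0.543,0.050,0.459,0.662
Alanine aminotransferase ALT (U/L),0.843,0.836,0.033,0.791,0.889
Aspartate aminotransferase AST (U/L),0.727,0.577,0.053,0.462,0.694
Alkaline phosphotase (U/L),2.992,1.966,0.086,1.825,2.184
Blood urea nitrogen (mg/dL),0.840,0.875,0.088,0.718,1.061
Total calcium (mg/dL),0.671,0.610,0.053,0.528,0.753
Cholesterol (mg/dL),0.373,0.793,0.086,0.680,1.076
Bicarbonate (mmol/L),3.769,1.840,0.089,1.661,2.035
Creatinine (mg/dL),3.286,3.041,0.189,2.491,3.370
Gamma glutamyl transferase (U/L),1.023,0.689,0.045,0.628,0.823
"Glucose, serum (mg/dL)",4.911,2.487,0.168,2.140,2.742
"Iron, refigerated (ug/dL)",1.752,1.443,0.088,1.288,1.559
Lactate dehydrogenase (U/L),1.050,1.102,0.066,0.973,1.202
Phosphorus (mg/dL),0.556,0.587,0.040,0.514,0.668
Total bilirubin (mg/dL),3.366,2.555,0.291,1.841,2.853
Total protein (g/dL),0.639,0.930,0.064,0.820,1.055
Triglycerides (mg/dL),0.987,1.285,0.170,1.126,1.867
Uric acid (mg/dL),2.598,2.401,0.116,2.232,2.675
Sodium (mmol/L),0.957,0.299,0.034,0.242,0.366
Potassium (mmol/L),0.654,0.664,0.059,0.559,0.778
Chloride (mmol/L),2.810,1.629,0.065,1.460,1.726
Osmolality (mmol/Kg),0.749,1.165,0.061,1.019,1.263
Globulin (g/dL),0.501,0.679,0.062,0.529,0.778
Total Cholesterol (mg/dL),0.457,0.609,0.058,0.488,0.714
"Albumin, urine (ug/mL)",1.247,1.459,0.085,1.326,1.680
"Creatinine, urine (umol/L)",0.963,0.992,0.108,0.769,1.193
First albumin creatinine ratio (mg/g),0.723,0.787,0.118,0.636,1.110
Second albumin (ug/mL),0.975,2.314,1.184,1.071,5.309
Second creatinine (mg/dL),1.768,2.056,0.525,1.459,3.329
Second albumin creatinine ratio (mg/g),1.176,3.321,0.825,1.783,5.326
The volume of urine collection #1,1.485,2.082,0.092,1.948,2.336
Urine #1 Flow Rate,3.262,2.921,0.720,1.743,4.456
Urine osmolality (mOsm/kg),1.308,1.675,0.179,1.352,2.242
Hepatitis A Antibody,0.031,0.089,0.028,0.046,0.151
Hepatitis B surface antibody,0.034,0.051,0.018,0.023,0.082
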