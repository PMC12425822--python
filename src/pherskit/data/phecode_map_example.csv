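icd,phecode,label,category,exclude_range
E08,249,Secondary diabetes mellitus,endocrine/metabolic,249-250.99
E10,250.1,Type 1 diabetes,endocrine/metabolic,249-250.99
E101,250.11,Type 1 diabetes with ketoacidosis,endocrine/metabolic,249-250.99
E11,250.2,Type 2 diabetes,endocrine/metabolic,"249-250.99,649.1-649.19"
E111,250.21,Type 2 diabetes with ketoacidosis,endocrine/metabolic,"249-250.99,649.1-649.19"
O26,649,Conditions complicating pregnancy,pregnancy complications,649-649.99
O244,649.1,Diabetes or abnormal glucose tolerance complicating pregnancy,pregnancy complications,649-649.99
C61,185,Cancer of prostate,neoplasms,185-187.99
C50,174.1,Breast cancer,neoplasms,174-175.99
M17,740.1,Osteoarthrosis of knee,musculoskeletal,740-740.99
M16,740.2,Osteoarthrosis of hip,musculoskeletal,740-740.99
I10,401.1,Essential hypertension,circulatory system,401-401.99
I11,401.21,Hypertensive heart disease,circulatory system,401-401.99
E66,278.1,Obesity,endocrine/metabolic,278-278.99
F10,317,Alcohol abuse,mental disorders,317-317.99
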