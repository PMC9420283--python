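outcome_id,exposure_category,comparison,srre,ci_lower,ci_upper,n_studies,i_squared,p_heterogeneity,first_author,pub_year,funding_source
breast_cancer,total_dairy,high vs. low,0.85,0.76,0.95,10,54.5,0.012,Dong,2011,National Natural Science Foundation of China
colorectal_cancer,total_dairy,high vs. low,0.83,0.76,0.89,18,61,,Schwingshackl,2018,None
cvd,total_dairy,high vs. low,0.90,0.81,0.99,10,55.8,0.009,Gholami,2017,None
t2d,total_dairy,high vs. low,0.91,0.85,0.97,21,63,0.0001,Schwingshackl,2017,NHS BRC grant (Interventional Public Health)
stroke,total_dairy,high vs. low,0.88,0.82,0.95,16,63.1,0.000,Gholami,2017,None
hypertension,total_dairy,high vs. low,0.89,0.86,0.93,9,0,0.65,Schwingshackl,2017,None
colorectal_cancer,milk,high vs. low,0.81,0.76,0.86,20,23.6,0.138,Jin,2020,National Research Foundation of Korea
t2d,milk,high vs. low,0.87,0.78,0.96,7,52.2,0.01,Tian,2017,National Natural Science Foundation of China; Wu Lian De Grant of Harbin Medical University
breast_cancer,low_fat_dairy,high vs. low,0.84,0.73,0.96,4,53.7,0.07,Dong,2011,National Natural Science Foundation of China
t2d,low_fat_dairy,high vs. low,0.83,0.76,0.90,9,0.0,0.67,Aune,2013,Liaison Committee between the Central Norway Regional Health Authority and the Norwegian University of Science and Technology
stroke,low_fat_dairy,high vs. low,0.94,0.90,0.98,9,0.0,0.61,Gholami,2017,None
hypertension,low_fat_dairy,high vs. low,0.84,0.74,0.95,4,38,,Ralston,2012,"National Health and Medical Research Council, Australia"
colorectal_cancer,high_fat_dairy,high vs. low,0.68,0.53,0.87,2,71,0.06,Barrubes,2019,"Interprofessional Dairy Organization (NLAC), Spain"
stroke,high_fat_dairy,high vs. low,0.91,0.84,0.99,3,20.0,0.88,Alexander,2016,Dairy Research Institute
prostate_cancer,total_dairy,high vs. low,1.06,0.92,1.22,11,,,Huncharek,2008,
prostate_cancer,total_dairy,high vs. low,1.11,1.00,1.78,11,,,Gao,2005,
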