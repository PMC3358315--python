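name,cancer,histotype,age_min,c,m,n,sigma,r_sex,r_race,f_year
lung_scc,Lung SCC,SCC,30,79.1,11.41,0.57,7.3,0.25,1.33,-6.86
lung_ac,Lung AC,AC,30,83.8,9.79,0.65,9.4,0.64,0.89,33.20
stomach_ac,Stomach AC,AC,30,100.4,8.28,1.79,11.6,0.37,1.03,-9.48
esophagus_scc,Esophagus SCC,SCC,30,89.6,12.86,0.83,30.1,0.30,2.75,-15.98
esophagus_ac,Esophagus AC,AC,30,106.2,9.93,1.05,40.2,0.10,0.10,151.85
colon_ac,Colon AC,AC,30,83.4,7.99,1.23,3.8,0.74,1.07,-6.17
rectum_ac,Rectum AC,AC,30,85.2,9.67,1.36,14.2,0.55,0.42,-7.28
pancreas_ac,Pancreas AC,AC,30,89.2,10.02,1.42,14.9,0.73,0.94,-3.41
liver_ac,Liver AC,AC,30,99.6,9.76,1.09,29.9,0.23,0.92,85.55
kidney_ac,Kidney AC,AC,30,97.3,7.57,0.75,12.1,0.46,0.62,36.30
breast_ductal_ac,Breast AC 850,AC,20,58.3,8.64,1.25,8.7,1.00,0.82,22.36
breast_lobular_ac,Breast AC 852,AC,30,64.1,11.63,1.16,24.9,1.00,0.41,71.22
prostate_ac,Prostate AC,AC,40,67.5,14.08,0.87,4.5,1.00,1.55,43.75
ovarian_ac,Ovarian AC,AC,25,106.0,5.95,0.73,10.8,1.00,0.30,-1.39
corpus_uteri_ac,Corpus uteri AC,AC,30,78.7,8.80,0.73,9.6,1.00,0.24,-7.13
cervix_uteri_scc,Cervix uteri SCC,SCC,15,37.9,12.01,0.96,30.4,1.00,0.97,-49.99
cervix_uteri_ac,Cervix uteri AC,AC,30,74.2,8.42,0.90,100.5,1.00,0.15,36.99
larynx_scc,Larynx SCC,SCC,15,81.7,11.09,0.83,17.2,0.12,1.04,-6.71
anal_scc,Anal SCC,SCC,15,91.8,11.96,1.12,272.5,1.36,0.35,279.69
vulvar_scc,Vulvar SCC,SCC,15,106.4,6.02,1.47,73.8,1.00,0.37,96.00
lip_scc,Lip SCC,SCC,15,132.3,7.15,0.00,14.2,0.10,0.10,-30.12
tongue_scc,Tongue SCC,SCC,15,99.4,8.89,0.72,26.7,0.31,0.43,29.52
floor_of_mouth_scc,Floor of mouth SCC,SCC,15,89.8,11.97,0.71,44.4,0.24,0.53,-19.79
gum_other_mouth_scc,Gum/other mouth SCC,SCC,15,96.0,11.34,1.00,43.6,0.44,0.47,-5.05
tonsil_scc,Tonsil SCC,SCC,15,96.2,10.09,0.65,45.3,0.18,0.77,47.37
hypopharynx_scc,Hypopharynx SCC,SCC,15,98.9,11.21,0.47,35.2,0.12,0.74,-11.06
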