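response,term,coefficient
color_appearance,A,7.81
color_appearance,B,8.10
color_appearance,C,8.09
color_appearance,AB,0.0982
color_appearance,AC,-0.5233
color_appearance,BC,0.0804
color_appearance,ABC,-1.52
flavor_sweetness,A,7.32
flavor_sweetness,B,7.30
flavor_sweetness,C,7.54
flavor_sweetness,AB,1.95
flavor_sweetness,AC,-0.1775
flavor_sweetness,BC,1.70
flavor_sweetness,ABC,-6.69
consistency,A,7.88
consistency,B,8.09
consistency,C,7.94
consistency,AB,-0.8554
consistency,AC,-0.2395
consistency,BC,-0.1847
consistency,ABC,0.2665
mouthfeel,A,7.50
mouthfeel,B,7.54
mouthfeel,C,7.77
mouthfeel,AB,1.32
mouthfeel,AC,1.25
mouthfeel,BC,0.4053
mouthfeel,ABC,-12.13
overall_acceptability,A,7.05
overall_acceptability,B,7.77
overall_acceptability,C,7.96
overall_acceptability,AB,-0.2073
overall_acceptability,AC,0.6976
overall_acceptability,BC,-0.0605
overall_acceptability,ABC,-6.29
ph,A,3.91
ph,B,3.81
ph,C,3.88
ph,AB,0.0576
ph,AC,-0.0229
ph,BC,-0.1117
ph,ABC,-1.10
acidity,A,0.5835
acidity,B,0.5447
acidity,C,0.5476
acidity,AB,0.0361
acidity,AC,-0.0165
acidity,BC,0.0155
acidity,ABC,0.0307
tss,A,22.12
tss,B,22.53
tss,C,22.56
tss,AB,-6.43
tss,AC,3.26
tss,BC,-2.28
tss,ABC,-7.75
whc,A,43.82
whc,B,47.23
whc,C,46.00
whc,AB,-17.65
whc,AC,3.56
whc,BC,18.12
whc,ABC,76.62
syneresis,A,43.81
syneresis,B,49.73
syneresis,C,48.05
syneresis,AB,-20.61
syneresis,AC,1.27
syneresis,BC,13.49
syneresis,ABC,107.83
anthocyanin,A,36.55
anthocyanin,B,24.52
anthocyanin,C,23.77
anthocyanin,AB,11.45
anthocyanin,AC,33.51
anthocyanin,BC,2.17
anthocyanin,ABC,-247.71
total_phenol,A,42.26
total_phenol,B,30.81
total_phenol,C,29.79
total_phenol,AB,8.97
total_phenol,AC,39.45
total_phenol,BC,-4.91
total_phenol,ABC,-107.29
total_flavonoid,A,23.43
total_flavonoid,B,11.95
total_flavonoid,C,11.97
total_flavonoid,AB,-3.74
total_flavonoid,AC,-2.32
total_flavonoid,BC,-0.2499
total_flavonoid,ABC,13.41
dpph,A,59.49
dpph,B,51.51
dpph,C,51.92
dpph,AB,5.01
dpph,AC,3.08
dpph,BC,1.01
dpph,ABC,12.02
frap,A,8.85
frap,B,5.61
frap,C,5.40
frap,AB,-3.07
frap,AC,-2.48
frap,BC,1.09
frap,ABC,10.51
ascorbic_acid,A,48.84
ascorbic_acid,B,34.32
ascorbic_acid,C,32.97
ascorbic_acid,AB,0.4387
ascorbic_acid,AC,-8.04
ascorbic_acid,BC,1.66
ascorbic_acid,ABC,-9.77
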