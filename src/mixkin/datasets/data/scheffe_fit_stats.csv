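response,mean,sd,cv,r2,adj_r2,pred_r2,adeq_precision
color_appearance,7.98,0.09,0.12,0.9957,0.9932,0.9848,49.12
flavor_sweetness,7.54,0.02,0.29,0.9917,0.9867,0.9749,38.56
consistency,7.90,0.01,0.18,0.9844,0.9750,0.9480,33.50
mouthfeel,7.66,0.03,0.41,0.9710,0.9537,0.8936,22.64
overall_acceptability,7.57,0.11,0.20,0.9982,0.9971,0.9943,90.29
ph,3.85,0.06,0.15,0.9833,0.9733,0.9399,26.70
acidity,0.56,0.04,0.82,0.9256,0.8810,0.7516,12.99
tss,21.98,0.14,0.63,0.9713,0.9541,0.9069,27.05
whc,46.73,0.42,0.91,0.9883,,0.9638,36.66
syneresis,48.60,0.57,1.49,0.9789,0.9662,0.9347,26.70
anthocyanin,28.41,0.30,1.06,0.9981,0.9970,0.9940,82.86
total_phenol,35.36,0.53,1.50,0.9943,0.9908,0.9800,49.33
total_flavonoid,15.38,0.30,1.99,0.9960,0.9935,0.9866,58.67
dpph,54.81,0.27,0.50,0.9939,0.9902,0.9806,44.82
frap,6.43,0.10,1.61,0.9939,0.9902,0.9785,51.95
ascorbic_acid,38.14,0.25,0.38,0.9984,0.9974,0.9944,95.35
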