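run_id,dahi_pct,juice_pct,water_pct,color_appearance,flavor_sweetness,consistency,mouthfeel,overall_acceptability,ph,acidity,tss,whc,syneresis,anthocyanin,total_phenol,total_flavonoid,dpph,frap,ascorbic_acid
1,60.00,9.50,15.00,7.81,7.35,7.87,7.52,7.05,3.91,0.58,22.42,43.69,45.66,36.55,42.23,23.43,59.48,8.84,48.86
2,60.75,5.75,18.00,7.97,7.56,7.88,7.68,7.73,3.84,0.55,22.29,49.66,51.78,25.88,33.97,13.61,54.11,5.94,34.98
3,60.75,8.00,15.75,7.83,7.48,7.82,7.61,7.24,3.87,0.57,21.51,44.91,46.95,32.62,41.76,19.10,58.29,7.38,42.65
4,60.00,5.00,19.50,8.09,7.52,7.94,7.75,7.96,3.88,0.55,22.52,45.93,47.95,23.79,29.83,11.98,51.91,5.41,32.96
5,62.25,5.00,17.25,8.11,7.84,7.97,7.76,7.85,3.82,0.55,21.96,51.86,52.88,24.91,28.88,12.03,51.82,5.78,34.08
6,62.25,7.25,15.00,7.98,7.79,7.75,7.88,7.33,3.87,0.57,20.74,41.05,42.05,33.55,39.85,17.04,56.78,6.67,41.18
7,60.00,9.50,15.00,7.81,7.29,7.89,7.48,7.05,3.92,0.58,21.88,44.05,46.05,36.68,42.23,23.43,59.48,8.84,48.86
8,60.00,7.25,17.25,7.82,7.39,7.85,7.94,7.68,3.89,0.56,23.17,45.82,47.22,38.68,45.87,17.11,56.62,6.51,38.89
9,63.00,5.75,15.75,8.02,7.66,7.91,7.56,7.54,3.81,0.56,21.48,48.12,50.18,24.89,32.28,13.41,54.04,6.06,36.20
10,60.00,5.00,19.50,8.09,7.56,7.94,7.79,7.96,3.88,0.55,22.58,45.93,47.95,23.73,29.83,11.98,51.91,5.41,32.96
11,64.50,5.00,15.00,8.12,7.29,8.07,7.49,7.77,3.81,0.55,22.53,47.22,49.22,24.42,30.78,11.44,51.66,5.61,34.32
12,61.875,5.75,16.875,7.99,7.62,7.89,7.53,7.57,3.81,0.56,21.63,50.66,52.66,22.55,31.53,13.58,54.55,6.15,35.76
13,64.50,5.00,15.00,8.08,7.29,8.11,7.60,7.77,3.82,0.54,22.51,47.22,50.22,24.44,30.79,12.54,51.33,5.60,34.35
14,62.25,5.00,17.25,8.12,7.84,7.97,7.76,7.85,3.82,0.55,21.96,50.22,51.36,24.25,29.35,11.95,51.88,5.78,34.02
15,60.75,6.875,16.875,7.85,7.43,7.83,7.63,7.47,3.85,0.57,22.19,47.99,49.99,28.69,39.23,16.53,55.77,6.59,38.36
16,62.25,7.25,15.00,7.98,7.79,7.79,7.83,7.39,3.89,0.58,20.74,41.25,43.25,33.18,37.59,16.57,56.66,6.22,42.28
17,61.50,6.50,16.50,7.91,7.51,7.84,7.48,7.42,3.82,0.56,21.52,48.82,50.88,24.18,35.13,15.97,55.55,6.51,37.68
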