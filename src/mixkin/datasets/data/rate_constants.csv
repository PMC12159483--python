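index_name,temperature_C,order,k,r2,t_half
overall_acceptability,5,0,0.0694,0.915,59.73
overall_acceptability,15,0,0.0815,0.988,50.86
overall_acceptability,25,0,0.1279,0.941,32.41
overall_acceptability,5,1,0.0089,0.909,
overall_acceptability,15,1,0.0106,0.983,
overall_acceptability,25,1,0.0175,0.920,
overall_acceptability,5,2,0.0011,0.902,
overall_acceptability,15,2,0.0014,0.977,
overall_acceptability,25,2,0.0024,0.897,
acidity,5,0,0.0212,0.959,14.50
acidity,15,0,0.0262,0.968,11.74
acidity,25,0,0.0344,0.953,8.94
acidity,5,1,0.0283,0.973,
acidity,15,1,0.0339,0.976,
acidity,25,1,0.0413,0.979,
acidity,5,2,0.0383,0.982,
acidity,15,2,0.0445,0.978,
acidity,25,2,0.0510,0.991,
ffa,5,0,0.0191,0.898,10.99
ffa,15,0,0.0255,0.945,8.24
ffa,25,0,0.0305,0.970,6.89
ffa,5,1,0.0329,0.862,
ffa,15,1,0.0412,0.889,
ffa,25,1,0.0442,0.932,
ffa,5,2,0.0583,0.808,
ffa,15,2,0.0690,0.819,
ffa,25,2,0.0664,0.868,
tba,5,0,0.0016,0.960,6.72
tba,15,0,0.0021,0.970,5.12
tba,25,0,0.0027,0.972,3.98
tba,5,1,0.0489,0.911,
tba,15,1,0.0573,0.916,
tba,25,1,0.0659,0.907,
tba,5,2,1.5344,0.845,
tba,15,2,1.6530,0.822,
tba,25,2,1.7848,0.798,
total_plate_count,5,0,0.1646,0.974,9.33
total_plate_count,15,0,0.2066,0.932,7.43
total_plate_count,25,0,0.2322,0.956,6.61
total_plate_count,5,1,0.0382,0.961,
total_plate_count,15,1,0.0451,0.888,
total_plate_count,25,1,0.0491,0.915,
total_plate_count,5,2,0.0091,0.925,
total_plate_count,15,2,0.0102,0.833,
total_plate_count,25,2,0.0108,0.857,
yeast_mold,5,0,0.1715,0.888,6.43
yeast_mold,15,0,0.1816,0.854,6.07
yeast_mold,25,0,0.2403,0.901,4.59
yeast_mold,5,1,0.0541,0.912,
yeast_mold,15,1,0.0561,0.894,
yeast_mold,25,1,0.6560,0.958,
yeast_mold,5,2,0.0178,0.922,
yeast_mold,15,2,0.0181,0.920,
yeast_mold,25,2,0.0191,0.989,
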