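index_name,temperature_C,day,value,sd,units,direction
anthocyanin,5,0,37.91,0.11,umol/100 g,decreasing
anthocyanin,5,3,37.36,0.09,umol/100 g,decreasing
anthocyanin,5,6,37.07,0.07,umol/100 g,decreasing
anthocyanin,5,9,36.67,0.21,umol/100 g,decreasing
anthocyanin,5,12,36.25,0.18,umol/100 g,decreasing
anthocyanin,5,15,35.39,0.26,umol/100 g,decreasing
anthocyanin,15,0,37.91,0.11,umol/100 g,decreasing
anthocyanin,15,3,37.31,0.16,umol/100 g,decreasing
anthocyanin,15,6,37.09,0.11,umol/100 g,decreasing
anthocyanin,15,9,36.79,0.17,umol/100 g,decreasing
anthocyanin,15,12,36.09,0.11,umol/100 g,decreasing
anthocyanin,15,15,35.19,0.11,umol/100 g,decreasing
anthocyanin,25,0,37.91,0.11,umol/100 g,decreasing
anthocyanin,25,3,36.99,0.18,umol/100 g,decreasing
anthocyanin,25,6,36.14,0.17,umol/100 g,decreasing
anthocyanin,25,9,35.96,0.28,umol/100 g,decreasing
anthocyanin,25,12,35.31,0.21,umol/100 g,decreasing
anthocyanin,25,15,34.96,0.14,umol/100 g,decreasing
total_phenol,5,0,44.14,0.28,mg GAE/100 g,decreasing
total_phenol,5,3,44.27,0.65,mg GAE/100 g,decreasing
total_phenol,5,6,43.76,0.32,mg GAE/100 g,decreasing
total_phenol,5,9,43.15,0.02,mg GAE/100 g,decreasing
total_phenol,5,12,42.55,0.30,mg GAE/100 g,decreasing
total_phenol,5,15,42.15,0.16,mg GAE/100 g,decreasing
total_phenol,15,0,44.14,0.28,mg GAE/100 g,decreasing
total_phenol,15,3,43.17,0.08,mg GAE/100 g,decreasing
total_phenol,15,6,42.43,0.14,mg GAE/100 g,decreasing
total_phenol,15,9,41.92,0.13,mg GAE/100 g,decreasing
total_phenol,15,12,41.33,0.27,mg GAE/100 g,decreasing
total_phenol,15,15,40.96,0.14,mg GAE/100 g,decreasing
total_phenol,25,0,44.14,0.28,mg GAE/100 g,decreasing
total_phenol,25,3,43.10,0.13,mg GAE/100 g,decreasing
total_phenol,25,6,42.42,0.04,mg GAE/100 g,decreasing
total_phenol,25,9,42.09,0.09,mg GAE/100 g,decreasing
total_phenol,25,12,40.34,0.15,mg GAE/100 g,decreasing
total_phenol,25,15,40.19,0.08,mg GAE/100 g,decreasing
total_flavonoid,5,0,22.62,0.18,mg QUE/100 g,decreasing
total_flavonoid,5,3,22.20,0.08,mg QUE/100 g,decreasing
total_flavonoid,5,6,21.93,0.11,mg QUE/100 g,decreasing
total_flavonoid,5,9,21.52,0.37,mg QUE/100 g,decreasing
total_flavonoid,5,12,21.11,0.05,mg QUE/100 g,decreasing
total_flavonoid,5,15,20.42,0.18,mg QUE/100 g,decreasing
total_flavonoid,15,0,22.62,0.18,mg QUE/100 g,decreasing
total_flavonoid,15,3,22.10,0.13,mg QUE/100 g,decreasing
total_flavonoid,15,6,21.74,0.22,mg QUE/100 g,decreasing
total_flavonoid,15,9,21.22,0.05,mg QUE/100 g,decreasing
total_flavonoid,15,12,20.78,0.16,mg QUE/100 g,decreasing
total_flavonoid,15,15,20.11,0.06,mg QUE/100 g,decreasing
total_flavonoid,25,0,22.62,0.18,mg QUE/100 g,decreasing
total_flavonoid,25,3,22.25,0.08,mg QUE/100 g,decreasing
total_flavonoid,25,6,21.57,0.23,mg QUE/100 g,decreasing
total_flavonoid,25,9,21.02,0.18,mg QUE/100 g,decreasing
total_flavonoid,25,12,20.32,0.18,mg QUE/100 g,decreasing
total_flavonoid,25,15,19.89,0.36,mg QUE/100 g,decreasing
ascorbic_acid,5,0,59.32,0.20,mg/100 g,decreasing
ascorbic_acid,5,3,59.17,0.13,mg/100 g,decreasing
ascorbic_acid,5,6,58.56,0.30,mg/100 g,decreasing
ascorbic_acid,5,9,57.56,0.12,mg/100 g,decreasing
ascorbic_acid,5,12,57.10,0.08,mg/100 g,decreasing
ascorbic_acid,5,15,56.75,0.13,mg/100 g,decreasing
ascorbic_acid,15,0,59.32,0.20,mg/100 g,decreasing
ascorbic_acid,15,3,58.62,0.21,mg/100 g,decreasing
ascorbic_acid,15,6,58.07,0.06,mg/100 g,decreasing
ascorbic_acid,15,9,56.22,0.28,mg/100 g,decreasing
ascorbic_acid,15,12,55.48,0.33,mg/100 g,decreasing
ascorbic_acid,15,15,52.59,0.21,mg/100 g,decreasing
ascorbic_acid,25,0,59.32,0.20,mg/100 g,decreasing
ascorbic_acid,25,3,56.66,0.30,mg/100 g,decreasing
ascorbic_acid,25,6,55.43,0.28,mg/100 g,decreasing
ascorbic_acid,25,9,51.33,0.14,mg/100 g,decreasing
ascorbic_acid,25,12,49.20,0.24,mg/100 g,decreasing
ascorbic_acid,25,15,47.65,0.17,mg/100 g,decreasing
ffa,5,0,0.42,0.01,ug/g,increasing
ffa,5,3,0.57,0.01,ug/g,increasing
ffa,5,6,0.60,0.01,ug/g,increasing
ffa,5,9,0.63,0.01,ug/g,increasing
ffa,5,12,0.66,0.01,ug/g,increasing
ffa,5,15,0.77,0.02,ug/g,increasing
ffa,15,0,0.42,0.01,ug/g,increasing
ffa,15,3,0.59,0.01,ug/g,increasing
ffa,15,6,0.67,0.02,ug/g,increasing
ffa,15,9,0.70,0.01,ug/g,increasing
ffa,15,12,0.78,0.02,ug/g,increasing
ffa,15,15,0.84,0.04,ug/g,increasing
ffa,25,0,0.46,0.01,ug/g,increasing
ffa,25,3,0.63,0.01,ug/g,increasing
ffa,25,6,0.71,0.02,ug/g,increasing
ffa,25,9,0.77,0.03,ug/g,increasing
ffa,25,12,0.84,0.02,ug/g,increasing
ffa,25,15,0.97,0.02,ug/g,increasing
tba,5,0,0.022,0.00,mg MDA/kg,increasing
tba,5,3,0.029,0.00,mg MDA/kg,increasing
tba,5,6,0.037,0.00,mg MDA/kg,increasing
tba,5,9,0.040,0.00,mg MDA/kg,increasing
tba,5,12,0.043,0.00,mg MDA/kg,increasing
tba,5,15,0.047,0.00,mg MDA/kg,increasing
tba,15,0,0.022,0.00,mg MDA/kg,increasing
tba,15,3,0.034,0.00,mg MDA/kg,increasing
tba,15,6,0.037,0.00,mg MDA/kg,increasing
tba,15,9,0.043,0.00,mg MDA/kg,increasing
tba,15,12,0.048,0.00,mg MDA/kg,increasing
tba,15,15,0.057,0.00,mg MDA/kg,increasing
tba,25,0,0.022,0.00,mg MDA/kg,increasing
tba,25,3,0.036,0.00,mg MDA/kg,increasing
tba,25,6,0.041,0.00,mg MDA/kg,increasing
tba,25,9,0.051,0.00,mg MDA/kg,increasing
tba,25,12,0.054,0.00,mg MDA/kg,increasing
tba,25,15,0.065,0.00,mg MDA/kg,increasing
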