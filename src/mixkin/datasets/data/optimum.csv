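response,predicted,observed_mean,observed_sd
color_appearance,7.796,7.85,0.45
flavor_sweetness,7.324,7.38,0.26
consistency,7.871,7.93,0.35
mouthfeel,7.598,7.78,0.18
overall_acceptability,7.156,8.29,0.10
ph,3.911,4.35,0.01
acidity,0.58,0.62,0.01
tss,22.362,22.42,0.08
whc,44.203,44.32,0.17
syneresis,46.047,46.30,0.36
anthocyanin,37.828,37.91,0.11
total_phenol,43.941,44.14,0.28
total_flavonoid,22.489,22.62,0.18
dpph,59.177,59.32,0.20
frap,8.447,8.30,0.21
ascorbic_acid,47.228,59.32,0.20
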