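index_name,c0,units
overall_acceptability,8.29,9-point hedonic
acidity,0.62,% lactic acid
ffa,0.42,ug/g
tba,0.022,mg MDA/kg
total_plate_count,3.07,log10 cfu/mL
yeast_mold,2.21,log10 cfu/mL
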