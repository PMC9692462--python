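molecule_id,site_id,medium,unit,functional,basis,BDE,IP,PDE,PA,ETE,SETPT,SPLET,IPH
ATV,1-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",91.4,107.0,22.4,23.8,105.7,129.4,129.4,38.1
ATV,2-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",104.2,,35.3,46.7,95.6,142.3,142.3,38.1
ATV,3-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",105.2,,36.3,61.5,81.8,143.2,143.2,38.1
ATV,4-NH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",90.2,,21.3,44.4,83.9,128.3,128.3,38.1
o-ATV,1-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",91.2,106.9,22.4,23.8,105.5,129.3,129.3,38.1
o-ATV,2-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",104.2,,35.4,46.8,95.5,142.3,142.3,38.1
o-ATV,3-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",105.1,,36.3,61.5,81.7,143.2,143.2,38.1
o-ATV,4-NH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",89.3,,20.5,49.0,78.4,127.4,127.4,38.1
o-ATV,5-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",77.5,,8.7,34.4,81.2,115.6,115.6,38.1
p-ATV,1-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",90.7,106.2,22.6,23.8,105.0,128.8,128.8,38.1
p-ATV,2-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",104.2,,36.0,46.8,95.4,142.2,142.2,38.1
p-ATV,3-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",105.1,,37.0,58.2,85.0,143.2,143.2,38.1
p-ATV,4-NH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",85.5,,17.4,43.8,79.0,123.6,123.6,38.1
p-ATV,5-OH,methanol,kcal/mol,B3LYP,"6-31+G(d,p)",77.4,,9.2,37.9,77.5,115.4,115.4,38.1
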