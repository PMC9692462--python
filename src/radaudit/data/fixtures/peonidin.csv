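molecule_id,site_id,medium,unit,functional,basis,BDE,IP,PDE,PA,ETE,SETPT,SPLET,IPH
peonidin,,gas,kcal/mol,B3LYP,"6-31+G(d,p)",81.50,235.37,159.88,-120.49,515.74,395.25,395.25,
peonidin,,water,kcal/mol,B3LYP,"6-31+G(d,p)",78.92,138.36,254.51,-88.96,483.38,392.87,394.42,
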