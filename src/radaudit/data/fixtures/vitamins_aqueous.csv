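molecule_id,site_id,medium,unit,functional,basis,BDE,IP,PDE,PA,ETE,SETPT,SPLET,IPH
vitamin A,,water,kJ/mol,,,,,,,,1742.0±2.0,532.0±1.0,1386.0
vitamin B1,,water,kJ/mol,,,,,,,,1750.5±0.5,611.5±1.5,1315.5
vitamin B3,,water,kJ/mol,,,,,,,,1790.5±1.5,658.0±2.0,1309.0
vitamin B6,,water,kJ/mol,,,,,,,,1655.0±1.0,537.0±0.0,1294.5
vitamin C,,water,kJ/mol,,,,,,,,1611.5±1.5,495.0±2.0,1293.0
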