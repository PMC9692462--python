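molecule_id,site_id,medium,unit,functional,basis,BDE,IP,PDE,PA,ETE,SETPT,SPLET,IPH
vitamin B3,,gas,kJ/mol,UB3LYP,"6-311G(d,p)",437.1,879.9,878.7,1432.5,326.1,1758.6,1758.6,1321.5
vitamin B3,,gas,kJ/mol,ROB3LYP,"6-311G(d,p)",443.6,884.3,880.8,1432.5,332.6,1765.1,1765.1,1321.5
vitamin B3,,gas,kJ/mol,UB3LYP,"6-311++G(d,p)",438.6,891.8,868.6,1397.4,363.0,1760.4,1760.4,1321.8
vitamin B3,,gas,kJ/mol,ROB3LYP,"6-311++G(d,p)",445.3,896.1,870.9,1397.4,369.6,1767.1,1767.1,1321.8
vitamin B3,,water,kJ/mol,UB3LYP,"6-311G(d,p)",436.3,584.2,18.6,154.2,448.6,602.8,602.8,166.5
vitamin B3,,water,kJ/mol,ROB3LYP,"6-311G(d,p)",442.7,588.5,20.7,154.2,455.1,609.2,609.2,166.5
vitamin B3,,water,kJ/mol,UB3LYP,"6-311++G(d,p)",437.2,595.1,8.9,117.8,486.2,604.0,604.0,166.8
vitamin B3,,water,kJ/mol,ROB3LYP,"6-311++G(d,p)",443.9,599.5,11.2,117.8,492.9,610.7,610.7,166.8
vitamin B3 (reported),,water,kJ/mol,B3LYP,6-311G**,441,892,869,149,478,1761,627,1320
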