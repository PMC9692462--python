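medium,functional,basis,kcal_per_mol,kJ_per_mol,eV,erratum
gas,B3LYP,"6-311++G(d,p)",315.9,1321.8,13.699,
gas,B3LYP,"6-311+G(d,p)",315.8,1321.5,13.696,
gas,B3LYP,"6-31++G(d,p)",315.5,1320.2,13.683,
gas,B3LYP,"6-31+G(d,p)",314.7,1316.5,13.645,
gas,PBE0,"6-311++G(d,p)",315.2,1318.8,13.669,
gas,PBE0,"6-311+G(d,p)",315.8,1321.5,13.696,duplicated_row
gas,PBE0,"6-31++G(d,p)",314.7,1316.9,13.649,
gas,PBE0,"6-31+G(d,p)",313.9,1313.5,13.613,
gas,M062x,"6-311++G(d,p)",313.4,1311.1,13.589,
gas,M062x,"6-311+G(d,p)",313.3,1310.9,13.587,
gas,M062x,"6-31++G(d,p)",313.4,1311.4,13.591,
gas,M062x,"6-31+G(d,p)",312.4,1307.1,13.547,
gas,M052x,"6-311++G(d,p)",314.0,1314.0,13.618,
gas,M052x,"6-311+G(d,p)",314.0,1313.8,13.616,
gas,M052x,"6-31++G(d,p)",314.1,1314.4,13.623,
gas,M052x,"6-31+G(d,p)",313.2,1310.3,13.581,
benzene,B3LYP,"6-311++G(d,p)",93.9,393.0,4.073,
benzene,B3LYP,"6-311+G(d,p)",93.9,392.7,4.070,
benzene,B3LYP,"6-31++G(d,p)",93.5,391.4,4.057,
benzene,B3LYP,"6-31+G(d,p)",92.7,387.7,4.019,
benzene,PBE0,"6-311++G(d,p)",93.2,390.0,4.042,
benzene,PBE0,"6-311+G(d,p)",93.9,392.7,4.070,duplicated_row
benzene,PBE0,"6-31++G(d,p)",92.8,388.1,4.022,
benzene,PBE0,"6-31+G(d,p)",91.9,384.7,3.987,
benzene,M062x,"6-311++G(d,p)",91.4,382.3,3.962,
benzene,M062x,"6-311+G(d,p)",91.3,382.1,3.961,
benzene,M062x,"6-31++G(d,p)",91.4,382.6,3.965,
benzene,M062x,"6-31+G(d,p)",90.4,378.3,3.921,
benzene,M052x,"6-311++G(d,p)",92.1,385.2,3.992,
benzene,M052x,"6-311+G(d,p)",92.0,384.9,3.990,
benzene,M052x,"6-31++G(d,p)",92.2,385.6,3.996,
benzene,M052x,"6-31+G(d,p)",91.2,381.5,3.954,
toluene,B3LYP,"6-311++G(d,p)",84.8,354.9,3.678,
toluene,B3LYP,"6-311+G(d,p)",84.7,354.6,3.675,
toluene,B3LYP,"6-31++G(d,p)",84.4,353.3,3.662,
toluene,B3LYP,"6-31+G(d,p)",83.6,349.6,3.624,
toluene,PBE0,"6-311++G(d,p)",84.1,351.9,3.648,
toluene,PBE0,"6-311+G(d,p)",84.7,354.6,3.675,duplicated_row
toluene,PBE0,"6-31++G(d,p)",83.7,350.0,3.628,
toluene,PBE0,"6-31+G(d,p)",82.8,346.6,3.592,
toluene,M062x,"6-311++G(d,p)",82.3,344.2,3.567,
toluene,M062x,"6-311+G(d,p)",82.2,344.0,3.566,
toluene,M062x,"6-31++G(d,p)",82.3,344.5,3.570,
toluene,M062x,"6-31+G(d,p)",81.3,340.2,3.526,
toluene,M052x,"6-311++G(d,p)",83.0,347.1,3.597,
toluene,M052x,"6-311+G(d,p)",82.9,346.8,3.595,
toluene,M052x,"6-31++G(d,p)",83.0,347.5,3.601,
toluene,M052x,"6-31+G(d,p)",82.1,343.4,3.559,
ethanol,B3LYP,"6-311++G(d,p)",41.0,171.5,1.777,
ethanol,B3LYP,"6-311+G(d,p)",40.9,171.2,1.774,
ethanol,B3LYP,"6-31++G(d,p)",40.6,169.9,1.761,
ethanol,B3LYP,"6-31+G(d,p)",39.7,166.2,1.722,chain_rounded:eV
ethanol,PBE0,"6-311++G(d,p)",40.3,168.5,1.747,
ethanol,PBE0,"6-311+G(d,p)",40.9,171.2,1.774,duplicated_row
ethanol,PBE0,"6-31++G(d,p)",39.8,166.6,1.727,
ethanol,PBE0,"6-31+G(d,p)",39.0,163.2,1.691,
ethanol,M062x,"6-311++G(d,p)",38.4,160.8,1.666,
ethanol,M062x,"6-311+G(d,p)",38.4,160.6,1.665,
ethanol,M062x,"6-31++G(d,p)",38.5,161.1,1.669,
ethanol,M062x,"6-31+G(d,p)",37.5,156.8,1.625,
ethanol,M052x,"6-311++G(d,p)",39.1,163.7,1.696,
ethanol,M052x,"6-311+G(d,p)",39.1,163.4,1.694,
ethanol,M052x,"6-31++G(d,p)",39.2,164.1,1.701,
ethanol,M052x,"6-31+G(d,p)",38.2,160.0,1.659,
methanol,B3LYP,"6-311++G(d,p)",39.3,164.6,1.705,
methanol,B3LYP,"6-311+G(d,p)",39.3,164.3,1.703,
methanol,B3LYP,"6-31++G(d,p)",39.0,163.0,1.690,chain_rounded:eV
methanol,B3LYP,"6-31+G(d,p)",38.1,159.3,1.651,
methanol,PBE0,"6-311++G(d,p)",38.6,161.6,1.675,
methanol,PBE0,"6-311+G(d,p)",39.3,164.3,1.703,duplicated_row
methanol,PBE0,"6-31++G(d,p)",38.2,159.7,1.656,chain_rounded:eV
methanol,PBE0,"6-31+G(d,p)",37.3,156.3,1.619,chain_rounded:eV
methanol,M062x,"6-311++G(d,p)",36.8,153.9,1.595,
methanol,M062x,"6-311+G(d,p)",36.7,153.7,1.593,
methanol,M062x,"6-31++G(d,p)",36.8,154.2,1.598,
methanol,M062x,"6-31+G(d,p)",35.8,149.9,1.553,
methanol,M052x,"6-311++G(d,p)",37.5,156.8,1.625,
methanol,M052x,"6-311+G(d,p)",37.4,156.5,1.622,
methanol,M052x,"6-31++G(d,p)",37.6,157.2,1.629,
methanol,M052x,"6-31+G(d,p)",36.6,153.1,1.587,
water,B3LYP,"6-311++G(d,p)",39.4,164.9,1.709,
water,B3LYP,"6-311+G(d,p)",39.3,164.6,1.706,
water,B3LYP,"6-31++G(d,p)",39.0,163.3,1.692,
water,B3LYP,"6-31+G(d,p)",38.2,159.6,1.655,
water,PBE0,"6-311++G(d,p)",38.7,161.9,1.678,
water,PBE0,"6-311+G(d,p)",39.3,164.6,1.706,duplicated_row
water,PBE0,"6-31++G(d,p)",38.2,160.0,1.658,
water,PBE0,"6-31+G(d,p)",37.4,156.6,1.623,
water,M062x,"6-311++G(d,p)",36.9,154.2,1.598,
water,M062x,"6-311+G(d,p)",36.8,154.0,1.596,
water,M062x,"6-31++G(d,p)",36.9,154.5,1.601,
water,M062x,"6-31+G(d,p)",35.9,150.1,1.556,chain_rounded:kJ_per_mol
water,M052x,"6-311++G(d,p)",37.5,157.1,1.628,
water,M052x,"6-311+G(d,p)",37.5,156.8,1.626,
water,M052x,"6-31++G(d,p)",37.6,157.5,1.632,
water,M052x,"6-31+G(d,p)",36.7,153.4,1.590,
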