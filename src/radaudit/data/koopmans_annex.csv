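medium,functional,basis,kcal_per_mol,kJ_per_mol,eV
gas,B3LYP,"6-311++G(d,p)",202.3,846.5,8.774
gas,B3LYP,"6-311+G(d,p)",201.9,844.6,8.754
gas,B3LYP,"6-31++G(d,p)",202.5,847.3,8.782
gas,B3LYP,"6-31+G(d,p)",198.4,830.1,8.603
gas,PBE0,"6-311++G(d,p)",210.5,880.8,9.128
gas,PBE0,"6-311+G(d,p)",210.1,878.9,9.109
gas,PBE0,"6-31++G(d,p)",210.6,881.0,9.131
gas,PBE0,"6-31+G(d,p)",206.9,865.8,8.973
benzene,B3LYP,"6-311++G(d,p)",200.9,840.5,8.711
benzene,B3LYP,"6-311+G(d,p)",200.6,839.1,8.697
benzene,B3LYP,"6-31++G(d,p)",201.1,841.4,8.721
benzene,B3LYP,"6-31+G(d,p)",197.6,826.6,8.567
benzene,PBE0,"6-311++G(d,p)",209.1,874.8,9.067
benzene,PBE0,"6-311+G(d,p)",208.8,873.5,9.053
benzene,PBE0,"6-31++G(d,p)",209.2,875.3,9.071
benzene,PBE0,"6-31+G(d,p)",206.1,862.3,8.937
toluene,B3LYP,"6-311++G(d,p)",200.8,840.3,8.709
toluene,B3LYP,"6-311+G(d,p)",200.5,839.0,8.695
toluene,B3LYP,"6-31++G(d,p)",201.2,841.2,8.719
toluene,B3LYP,"6-31+G(d,p)",197.5,826.5,8.566
toluene,PBE0,"6-311++G(d,p)",209.0,874.6,9.064
toluene,PBE0,"6-311+G(d,p)",208.7,873.3,9.051
toluene,PBE0,"6-31++G(d,p)",209.1,875.1,9.070
toluene,PBE0,"6-31+G(d,p)",206.1,862.1,8.935
ethanol,B3LYP,"6-311++G(d,p)",199.9,836.2,8.667
ethanol,B3LYP,"6-311+G(d,p)",199.6,835.3,8.657
ethanol,B3LYP,"6-31++G(d,p)",200.1,837.2,8.677
ethanol,B3LYP,"6-31+G(d,p)",197.0,824.0,8.541
ethanol,PBE0,"6-311++G(d,p)",208.1,870.5,9.022
ethanol,PBE0,"6-311+G(d,p)",207.9,869.6,9.013
ethanol,PBE0,"6-31++G(d,p)",205.5,859.7,8.910
ethanol,PBE0,"6-31+G(d,p)",208.2,871.1,9.029
methanol,B3LYP,"6-311++G(d,p)",199.8,836.1,8.665
methanol,B3LYP,"6-311+G(d,p)",199.6,835.2,8.656
methanol,B3LYP,"6-31++G(d,p)",200.1,837.1,8.676
methanol,B3LYP,"6-31+G(d,p)",196.9,824.0,8.540
methanol,PBE0,"6-311++G(d,p)",208.0,870.4,9.021
methanol,PBE0,"6-311+G(d,p)",207.8,869.6,9.012
methanol,PBE0,"6-31++G(d,p)",208.2,871.0,9.028
methanol,PBE0,"6-31+G(d,p)",205.5,859.7,8.910
water,B3LYP,"6-311++G(d,p)",199.8,835.9,8.663
water,B3LYP,"6-311+G(d,p)",199.6,835.0,8.654
water,B3LYP,"6-31++G(d,p)",200.0,837.0,8.674
water,B3LYP,"6-31+G(d,p)",196.9,823.9,8.539
water,PBE0,"6-311++G(d,p)",208.0,870.2,9.019
water,PBE0,"6-311+G(d,p)",207.8,869.4,9.011
water,PBE0,"6-31++G(d,p)",208.1,870.9,9.026
water,PBE0,"6-31+G(d,p)",205.4,859.5,8.908
gas,M062x,"6-31+G(d,p)",233.4,976.7,10.122
benzene,M062x,"6-31+G(d,p)",232.6,973.2,10.086
toluene,M062x,"6-31+G(d,p)",232.6,973.1,10.085
ethanol,M062x,"6-31+G(d,p)",232.0,970.7,10.060
methanol,M062x,"6-31+G(d,p)",232.0,970.6,10.060
water,M062x,"6-31+G(d,p)",232.0,970.5,10.058
gas,M052x,"6-31+G(d,p)",237.1,992.1,10.282
benzene,M052x,"6-31+G(d,p)",236.3,988.6,10.246
toluene,M052x,"6-31+G(d,p)",236.3,988.5,10.245
ethanol,M052x,"6-31+G(d,p)",235.7,986.1,10.221
methanol,M052x,"6-31+G(d,p)",235.7,986.1,10.220
water,M052x,"6-31+G(d,p)",235.7,986.0,10.220
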