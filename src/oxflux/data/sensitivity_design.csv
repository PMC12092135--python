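parameter_path,label,base,low,high,printed_d18O_change,printed_cap17O_change,printed_d18O_rank,printed_cap17O_rank
faecal_water_fraction,faecal H2O content,0.55,0.30,0.90,0.00,0,21,26
ouf,oxygen utilization fraction,0.25,0.05,0.45,1.70,38,8,2
z_value_permil,z-value,10.5,4,12,3.01,40,2,1
body_temp_C,body temperature,38,34,40,0.50,1,14,24
meeh_k,Meeh factor,1100,900,1300,0.31,0,16,26
skin_evap_rate,skin H2O evaporation rate,0.025,0.001,0.1,5.12,4,1,13
rel_humidity,relative humidity,0.45,0.0,1.0,2.29,2,4,17
ambient_temp_C,environmental temperature,25,0,40,1.35,2,10,16
preformed_water.d18O,pre-formed water d18O,-4,0,-6,1.63,7,9,11
preformed_water.cap17O,pre-formed water cap17O,20,0,40,0,12,21,8
atmospheric_O2.d18O,atmospheric O2 d18O,24.046,20,27,1.87,9,6,10
atmospheric_O2.cap17O,atmospheric O2 cap17O,-441,-520,-360,0,29,21,4
digestibility_D,relative digestibility,0.85,0.40,0.90,2.88,2,3,17
water_leakage_fraction,water nozzle leakage,0.10,0.0,0.30,0.39,11,15,9
energy_extraction_E,energy extraction efficiency,1.00,0.80,1.00,1.02,1,11,25
food_water_content_WC,food free H2O content,0.09,0.0,0.25,1.72,5,7,12
food_free_water.d18O,food d18O,-16.41,-25,0,0.82,4,12,14
food_free_water.cap17O,food cap17O,30,0,50,0,1,21,23
cellulose.corn,corn cellulose d18O,26,22,30,0.27,2,18,20
cellulose.wheat,wheat cellulose d18O,26.9,22,30,0.31,2,16,17
cellulose.soybean,soybean cellulose d18O,25.9,22,30,0.22,2,19,22
theta_set.exhaled_co2,theta exhaled CO2,0.5248,0.522,0.526,0,32,21,3
theta_set.bound_oxygen,theta cellulose to pre-formed water,0.525,0.525,0.530,0,28,21,5
theta_set.transcutaneous,theta transcutaneous vapour,0.5235,0.516,0.525,0,13,21,7
alpha18_transcutaneous,alpha18 transcutaneous vapour,0.982,0.976,0.99,0.74,2,13,21
theta_set.oxidase_water,theta lung-absorbed O2,0.5179,0.5166,0.519,0,3,21,15
alpha18_overrides.oxidase_water,alpha18 lung-absorbed O2,0.994,0.99,1.0,2.07,27,5,6
exhaled_split,oral/nasal routing of exhaled vapour,0.5 & 0.25,0.0625 & 0.6875,0.4375 & 0.3125,0.02,0,20,26
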