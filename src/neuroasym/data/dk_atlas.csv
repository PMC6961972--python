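region,pfit,total_surface_area_mm2,mean_thickness_mm,da_frac_surface_area,da_frac_volume,da_frac_thickness
bankssts,0,1900.0,2.45,0.018,0.015,0.006
caudalanteriorcingulate,0,1400.0,2.60,-0.022,-0.018,-0.008
caudalmiddlefrontal,1,4100.0,2.48,0.009,0.008,0.003
cuneus,0,2600.0,1.85,-0.012,-0.010,-0.004
entorhinal,0,722.9,3.30,0.025,0.020,0.009
frontalpole,1,900.0,2.75,-0.020,-0.016,-0.007
fusiform,1,6100.0,2.65,0.008,0.007,0.003
inferiorparietal,1,8600.0,2.40,-0.015,-0.013,-0.005
inferiortemporal,0,6100.0,2.70,0.010,0.009,0.004
insula,0,4200.0,2.95,-0.007,-0.006,-0.002
isthmuscingulate,0,1800.0,2.35,0.016,0.013,0.005
lateraloccipital,0,8900.0,2.10,-0.009,-0.008,-0.003
lateralorbitofrontal,1,4500.0,2.60,0.011,0.009,0.004
lingual,0,5300.0,1.95,-0.006,-0.005,-0.002
medialorbitofrontal,1,3300.0,2.40,0.014,0.012,0.005
middletemporal,0,6200.0,2.75,-0.011,-0.009,-0.004
paracentral,0,2500.0,2.30,0.012,0.010,0.004
parahippocampal,0,1300.0,2.65,-0.017,-0.014,-0.006
parsopercularis,0,2900.0,2.50,0.013,0.011,0.005
parsorbitalis,0,1200.0,2.65,-0.019,-0.015,-0.006
parstriangularis,0,2500.0,2.45,0.010,0.008,0.003
pericalcarine,0,2400.0,1.65,-0.013,-0.011,-0.004
postcentral,0,7400.0,2.00,0.007,0.006,0.002
posteriorcingulate,0,2200.0,2.40,-0.005,-0.004,-0.002
precentral,0,9000.0,2.55,0.006,0.005,0.002
precuneus,0,6900.0,2.30,-0.010,-0.008,-0.003
rostralanteriorcingulate,0,1500.0,2.75,0.021,0.017,0.007
rostralmiddlefrontal,1,10500.0,2.35,-0.008,-0.007,-0.003
superiorfrontal,1,12730.15,2.65,0.005,0.004,0.002
superiorparietal,1,9600.0,2.15,-0.014,-0.012,-0.005
superiortemporal,0,7000.0,2.70,0.015,0.012,0.005
supramarginal,1,7000.0,2.50,-0.016,-0.013,-0.005
temporalpole,0,800.0,3.45,0.023,0.019,0.008
transversetemporal,0,800.0,2.30,0.020,0.016,0.007
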