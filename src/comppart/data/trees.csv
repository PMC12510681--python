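# Simulated trembling aspen (Populus tremuloides) and white spruce (Picea glauca)
# mixtures, western Canada: stand volume (m3/ha), density in stems/ha.
# Full-density monocultures planted at the mixture's total density;
# partial-density monocultures at the species' density within the mixture.
mixture_id,species_id,ry_expected,yield_observed,mono_full_yield,mono_partial_yield,density_full,density_total_mixture,ability,age_or_time
Populus:Picea_20y_90:10,Populus,0.9,22.3,23.7,23.3,11000,11000,,20 years
Populus:Picea_20y_90:10,Picea,0.1,0.1,0.7,0.5,11000,11000,,20 years
Populus:Picea_20y_70:30,Populus,0.7,19.0,23.7,22.5,11000,11000,,20 years
Populus:Picea_20y_70:30,Picea,0.3,0.2,0.7,0.6,11000,11000,,20 years
Populus:Picea_20y_50:50,Populus,0.5,15.1,23.7,21.4,11000,11000,,20 years
Populus:Picea_20y_50:50,Picea,0.5,0.3,0.7,0.6,11000,11000,,20 years
Populus:Picea_20y_30:70,Populus,0.3,10.6,23.7,19.8,11000,11000,,20 years
Populus:Picea_20y_30:70,Picea,0.7,0.4,0.7,0.7,11000,11000,,20 years
Populus:Picea_20y_10:90,Populus,0.1,5.0,23.7,16.9,11000,11000,,20 years
Populus:Picea_20y_10:90,Picea,0.9,0.5,0.7,0.7,11000,11000,,20 years
Populus:Picea_40y_90:10,Populus,0.9,104.5,110.4,108.3,3600,3600,,40 years
Populus:Picea_40y_90:10,Picea,0.1,3.4,27.2,15.5,3600,3600,,40 years
Populus:Picea_40y_70:30,Populus,0.7,90.3,110.4,103.5,3600,3600,,40 years
Populus:Picea_40y_70:30,Picea,0.3,7.6,27.2,20.7,3600,3600,,40 years
Populus:Picea_40y_50:50,Populus,0.5,72.4,110.4,97.0,3600,3600,,40 years
Populus:Picea_40y_50:50,Picea,0.5,12.1,27.2,23.4,3600,3600,,40 years
Populus:Picea_40y_30:70,Populus,0.3,49.6,110.4,87.4,3600,3600,,40 years
Populus:Picea_40y_30:70,Picea,0.7,17.5,27.2,25.3,3600,3600,,40 years
Populus:Picea_40y_10:90,Populus,0.1,20.6,110.4,70.6,3600,3600,,40 years
Populus:Picea_40y_10:90,Picea,0.9,23.9,27.2,26.7,3600,3600,,40 years
Populus:Picea_60y_90:10,Populus,0.9,180.5,189.7,186.1,1800,1800,,60 years
Populus:Picea_60y_90:10,Picea,0.1,9.6,88.3,47.0,1800,1800,,60 years
Populus:Picea_60y_70:30,Populus,0.7,158.1,189.7,177.3,1800,1800,,60 years
Populus:Picea_60y_70:30,Picea,0.3,22.4,88.3,64.3,1800,1800,,60 years
Populus:Picea_60y_50:50,Populus,0.5,128.1,189.7,164.8,1800,1800,,60 years
Populus:Picea_60y_50:50,Picea,0.5,38.1,88.3,73.7,1800,1800,,60 years
Populus:Picea_60y_30:70,Populus,0.3,85.4,189.7,144.8,1800,1800,,60 years
Populus:Picea_60y_30:70,Picea,0.7,58.5,88.3,80.5,1800,1800,,60 years
Populus:Picea_60y_10:90,Populus,0.1,28.6,189.7,109.2,1800,1800,,60 years
Populus:Picea_60y_10:90,Picea,0.9,83.0,88.3,85.9,1800,1800,,60 years
Populus:Picea_80y_90:10,Populus,0.9,229.6,240.2,235.6,1100,1100,,80 years
Populus:Picea_80y_90:10,Picea,0.1,13.7,143.1,73.3,1100,1100,,80 years
Populus:Picea_80y_70:30,Populus,0.7,203.7,240.2,224.1,1100,1100,,80 years
Populus:Picea_80y_70:30,Picea,0.3,33.0,143.1,102.0,1100,1100,,80 years
Populus:Picea_80y_50:50,Populus,0.5,167.3,240.2,207.6,1100,1100,,80 years
Populus:Picea_80y_50:50,Picea,0.5,58.2,143.1,117.8,1100,1100,,80 years
Populus:Picea_80y_30:70,Populus,0.3,110.3,240.2,179.1,1100,1100,,80 years
Populus:Picea_80y_30:70,Picea,0.7,94.0,143.1,129.4,1100,1100,,80 years
Populus:Picea_80y_10:90,Populus,0.1,26.2,240.2,124.5,1100,1100,,80 years
Populus:Picea_80y_10:90,Picea,0.9,139.6,143.1,138.9,1100,1100,,80 years
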