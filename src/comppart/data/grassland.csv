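# Experimental grassland pot mixtures, six species, 13 weeks: aboveground
# biomass (g/pot), density in stems/pot. Full density 6 per pot; half-density
# monocultures (3 per pot) are the partial-density monocultures of the 50:50 mixtures.
mixture_id,species_id,ry_expected,yield_observed,mono_full_yield,mono_partial_yield,density_full,density_total_mixture,ability,age_or_time
Bromus:Dactylis,Bromus,0.5,2.6,5.5,5.3,6,6,,13 weeks
Bromus:Dactylis,Dactylis,0.5,8.6,9.8,11.5,6,6,,13 weeks
Bromus:Lotus,Bromus,0.5,3.8,5.5,5.3,6,6,,13 weeks
Bromus:Lotus,Lotus,0.5,3.2,6.3,4.7,6,6,,13 weeks
Bromus:Plantago,Bromus,0.5,1.9,5.5,5.3,6,6,,13 weeks
Bromus:Plantago,Plantago,0.5,10.9,8.6,16.1,6,6,,13 weeks
Bromus:Sanguisorba,Bromus,0.5,2.9,5.5,5.3,6,6,,13 weeks
Bromus:Sanguisorba,Sanguisorba,0.5,2.2,4.4,3.6,6,6,,13 weeks
Bromus:Trifolium,Bromus,0.5,3.8,5.5,5.3,6,6,,13 weeks
Bromus:Trifolium,Trifolium,0.5,9.3,13.3,14.2,6,6,,13 weeks
Dactylis:Lotus,Dactylis,0.5,11.8,9.8,11.5,6,6,,13 weeks
Dactylis:Lotus,Lotus,0.5,2.0,6.3,4.7,6,6,,13 weeks
Dactylis:Plantago,Dactylis,0.5,4.4,9.8,11.5,6,6,,13 weeks
Dactylis:Plantago,Plantago,0.5,9.5,8.6,16.1,6,6,,13 weeks
Dactylis:Sanguisorba,Dactylis,0.5,6.0,9.8,11.5,6,6,,13 weeks
Dactylis:Sanguisorba,Sanguisorba,0.5,1.9,4.4,3.6,6,6,,13 weeks
Dactylis:Trifolium,Dactylis,0.5,7.5,9.8,11.5,6,6,,13 weeks
Dactylis:Trifolium,Trifolium,0.5,7.7,13.3,14.2,6,6,,13 weeks
Lotus:Plantago,Lotus,0.5,1.0,6.3,4.7,6,6,,13 weeks
Lotus:Plantago,Plantago,0.5,16.2,8.6,16.1,6,6,,13 weeks
Lotus:Sanguisorba,Lotus,0.5,1.9,6.3,4.7,6,6,,13 weeks
Lotus:Sanguisorba,Sanguisorba,0.5,2.6,4.4,3.6,6,6,,13 weeks
Lotus:Trifolium,Lotus,0.5,2.4,6.3,4.7,6,6,,13 weeks
Lotus:Trifolium,Trifolium,0.5,9.2,13.3,14.2,6,6,,13 weeks
Plantago:Sanguisorba,Plantago,0.5,11.6,8.6,16.1,6,6,,13 weeks
Plantago:Sanguisorba,Sanguisorba,0.5,1.1,4.4,3.6,6,6,,13 weeks
Plantago:Trifolium,Plantago,0.5,10.2,8.6,16.1,6,6,,13 weeks
Plantago:Trifolium,Trifolium,0.5,6.9,13.3,14.2,6,6,,13 weeks
Sanguisorba:Trifolium,Sanguisorba,0.5,1.9,4.4,3.6,6,6,,13 weeks
Sanguisorba:Trifolium,Trifolium,0.5,13.4,13.3,14.2,6,6,,13 weeks
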