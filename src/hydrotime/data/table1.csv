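population,sample_site,mean_precip_mm,latitude_deg,longitude_deg,altitude_m,thousand_seed_weight_g,floristic_type,soil_type
PHA,"Peninsula Huemul Ranch, Neuquen",831,-40.95,-71.4167,1220,2.04,Shrub-grass steppe,"Fairly deep, volcanic"
PHB,"Peninsula Huemul Ranch, Neuquen",831,-41.0167,-71.3333,845,1.16,Shrub-grass steppe,"Deep, sandy"
SRA,"San Ramon Ranch, Rio Negro",584,-41.0167,-71.0667,1139,1.14,Grass steppe,Fairly deep sandy loam
SRB,"San Ramon Ranch, Rio Negro",584,-41.1167,-71.0167,890,0.94,Meadow,Deep sandy loam with high OSM
PA,"Pilcaniyeu Experimental Field, Rio Negro",264,-41.0667,-70.5667,1260,1.38,Shrub-grass steppe,Fairly deep sandy loam
PB,"Pilcaniyeu Experimental Field, Rio Negro",264,-41.05,-70.5,970,1.25,Meadow,"Deep loamy sand, alkaline, high OSM"
JA,"Ingeniero Jacobacci, Rio Negro",170,-41.9167,-69.2,1400,0.76,Grass steppe,Fairly deep sandy loam
JB,"Ingeniero Jacobacci, Rio Negro",170,-41.7667,-69.35,970,1.51,Salty Meadow,"Deep silty loam, saline-alkaline, high OSM"
SA,"Somuncura Plateau, Rio Negro",150,-41.4167,-66.9667,1430,1.1,Meadow,Fairly deep sandy loam
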