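taxon_id,subfamily,max_total_length,female_age_maturation,longevity_class,fecundity_class
taxon_1,Cyprininae,45.0,3.0,3,3
taxon_2,Oxygastrinae,30.0,2.0,2,3
taxon_3,Gobioninae,25.0,2.0,2,2
taxon_4,Cyprininae,60.0,3.5,3,3
taxon_5,Oxygastrinae,28.0,2.5,2,2
taxon_6,Gobioninae,15.0,1.0,1,1
taxon_7,Oxygastrinae,16.0,1.0,1,1
taxon_8,Gobioninae,12.0,1.0,1,1
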