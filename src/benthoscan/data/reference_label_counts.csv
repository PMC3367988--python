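taxon,human_labels
background,4764
Bathycrinus carpenterii,2524
Bathycrinus stalks,1729
Burrow,5701
Caulophacus arcticus,48
Caulophacus debris,131
Cladorhiza gelida,59
Purple anemone,498
Elpidia heckeri,551
Gersemia fructicosa,78
Kolga hyalina,172
Saduria megalura,67
Mohnia spp.,31
Small white sea anemone,2438
Small white sponge,637
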