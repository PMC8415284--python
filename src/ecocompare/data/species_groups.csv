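group_id,taxon_class,is_single_species,lifespan
Barracouta,vertebrate,1,10
Carpet shark,vertebrate,1,20
Demersal fish,vertebrate,0,20
Elasmobranch invert,vertebrate,0,10
Elasmobranch pisc,vertebrate,0,20
Flatfish,vertebrate,0,5
Kahawai,vertebrate,1,30
Leatherjacket,vertebrate,1,5
Mackerels,vertebrate,0,20
Mesopel fish invert,vertebrate,0,20
Pelagic fish lge,vertebrate,0,50
Pelagic fish sml,vertebrate,0,10
Pinniped,vertebrate,1,20
Red gurnard,vertebrate,1,20
Red cod,vertebrate,1,5
Reef fish invert,vertebrate,0,10
Reef fish pisc,vertebrate,0,10
Rig,vertebrate,1,20
School shark,vertebrate,1,50
Seabird,vertebrate,0,20
Snapper,vertebrate,1,50
Southern spiny dogfish,vertebrate,1,30
Tarakihi,vertebrate,1,40
Benthic Carniv,invertebrate,0,
Benthic grazer,invertebrate,0,
Carniv Zoo,invertebrate,0,
Cephalopod,invertebrate,0,2
Deposit feeder,invertebrate,0,
Dredge oysters,invertebrate,1,4
Filter other,invertebrate,0,
Gelat Zoo,invertebrate,0,
Invert comm Herb,invertebrate,0,6
Invert comm Scav,invertebrate,0,8
Macrobenth other,invertebrate,0,
Meiobenth,invertebrate,0,
MesoZoo,invertebrate,0,
MicroZoo,invertebrate,0,
Mussels,invertebrate,0,2
Scallops,invertebrate,1,2
Surf clams,invertebrate,0,2
Diatoms,producer,0,
Macroalgae,producer,1,
Microphytobenthos,producer,0,
Pico-phytoplankton,producer,0,
Carrion,bacteria_detritus,0,
Labile detritus,bacteria_detritus,0,
Pelagic bacteria,bacteria_detritus,0,
Refractory detritus,bacteria_detritus,0,
Sediment bacteria,bacteria_detritus,0,
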