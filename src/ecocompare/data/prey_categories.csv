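group_id,category
Barracouta,Teleost
Carpet shark,Elasmobranch
Demersal fish,Teleost
Elasmobranch invert,Elasmobranch
Elasmobranch pisc,Elasmobranch
Flatfish,Teleost
Kahawai,Teleost
Leatherjacket,Teleost
Mackerels,Teleost
Mesopel fish invert,Teleost
Pelagic fish lge,Teleost
Pelagic fish sml,Teleost
Pinniped,Cetacea
Red gurnard,Teleost
Red cod,Teleost
Reef fish invert,Teleost
Reef fish pisc,Teleost
Rig,Elasmobranch
School shark,Elasmobranch
Seabird,Bird
Snapper,Teleost
Southern spiny dogfish,Elasmobranch
Tarakihi,Teleost
Benthic Carniv,Polychaete
Benthic grazer,Echinoderm
Carniv Zoo,Crustacean
Cephalopod,Mollusc
Deposit feeder,Echinoderm
Dredge oysters,Mollusc
Filter other,Tunicate
Gelat Zoo,Coelenterate
Invert comm Herb,Mollusc
Invert comm Scav,Crustacean
Macrobenth other,Polychaete
Meiobenth,Crustacean
MesoZoo,Crustacean
MicroZoo,Microzooplankton
Mussels,Mollusc
Scallops,Mollusc
Surf clams,Mollusc
Diatoms,Phytoplankton
Macroalgae,Algae
Microphytobenthos,Algae
Pico-phytoplankton,Phytoplankton
Carrion,Detritus
Labile detritus,Detritus
Pelagic bacteria,Bacteria
Refractory detritus,Detritus
Sediment bacteria,Bacteria
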