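group_id,survey_r,cpue_r
Barracouta,-0.05,
Carpet shark,0.43,
Cephalopod,-0.15,
Demersal fish,0.48,
Elasmobranch Invert,0.16,
Elasmobranch Pisc,0.43,
Flatfish,0.3,
Leatherjacket,0.061,
Mackerels,-0.067,
Mesopel fish Invert,0.55,
Red cod,0.41,
Red gurnard,0.15,-0.059
Reef fish Pisc,-0.084,
Rig,-0.79,-0.37
Scallops,0.36,
School shark,0.79,
Snapper,0.13,0.66
Spiny dogfish,0.27,
Tarakihi,-0.2,
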