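group_id,w_inf_g,w_mat_g,k_vb,a_lw,b_lw,M_lit,beta,sigma,h,ks,gamma,alpha,f0,fc,w_egg_g,erepro,R_max
Barracouta,1856.216511755869,459.40485852242927,0.372017622924133,0.017443266182248,2.594177347887649,0.6531573599188428,11.441249626796708,1.0975267467582663,38.100014816436804,0.0,0.0026232260935403935,0.6,0.6,0.0,0.001,1.0,8.651427882981823
Carpet shark,5156.809984452377,2081.953415265836,0.1200014077186013,0.0112056843574519,2.870798024232581,0.3202583310153112,28.08343622736363,1.6484652057437483,17.276886135800446,0.0,0.0007557727839408488,0.6,0.6,0.0,0.001,1.0,30.503916650307417
Demersal fish,4375.9942606873765,1838.9797569485363,0.1449927604716844,0.0075127009177824,3.054584787015835,0.2267728513032296,26.939543546657664,1.6114068057126705,19.7632024822924,0.0,0.0008863929051895151,0.6,0.6,0.0,0.001,1.0,3.8831480227518673
Elasmobranch invert,2001.076839496885,668.8578917128904,0.3502457737304789,0.0094372363042951,3.4706980243949035,0.6319546201995878,15.182955884233404,1.2672798421225775,36.780100589051315,0.0,0.002161245036821648,0.6,0.6,0.0,0.001,1.0,8.649442901421766
Elasmobranch pisc,5282.817016869399,726.8491559353005,0.147034594574457,0.0054082400438988,2.654289492067548,0.2905110287523315,14.549289990357943,1.2230596647063638,21.339953645150523,0.0,0.0013022517807224775,0.6,0.6,0.0,0.001,1.0,3.1701383239593937
Flatfish,629.9896187253183,305.78397028843415,0.5404622922625809,0.0097105468475089,2.969555811275808,0.9538485094869714,17.482806957681614,1.2292191579378295,38.609598357169865,0.0,0.002322835354564998,0.6,0.6,0.0,0.001,1.0,5.274160174585189
Kahawai,3914.980525475728,1033.8180111951156,0.0848865615720676,0.0166030012967326,2.9371519188723307,0.2056196554220404,19.00725396723212,1.3749007328359082,11.148956774036696,0.0,0.0005968895730673527,0.6,0.6,0.0,0.001,1.0,197.2262504698511
Leatherjacket,591.9412946759957,112.80328608477484,0.7323697695343442,0.0211445474923642,2.8874783790301746,0.9923219109901418,8.017679010492532,0.6059123005417831,51.2438843834063,0.0,0.006512291351900648,0.6,0.6,0.0,0.001,1.0,21.287156261505963
Mackerels,4619.175800542134,521.45237068631,0.1252836310853085,0.0050663940356114,3.2869243775021384,0.288404007698961,12.607618203602168,1.1154125174705865,17.387397510605002,0.0,0.0011721826660927642,0.6,0.6,0.0,0.001,1.0,40.42318963002537
Mesopel fish invert,4768.129623544809,1913.584230527016,0.1463476212876092,0.0138527717064781,2.639796998127657,0.2314199414425488,28.348077762589565,1.6281416530544184,20.526761657106547,0.0,0.000908795770739159,0.6,0.6,0.0,0.001,1.0,7.158647107925699
Pelagic fish lge,17902.186026590767,4690.252664787518,0.0623950675208479,0.0196904128348481,3.134718320000591,0.110339611553473,41.639486336779896,1.896244231655865,13.602050039532154,0.0,0.0005066243954132689,0.6,0.6,0.0,0.001,1.0,4.3935796864500665
Pelagic fish sml,1374.227616271608,256.6748592403277,0.2263931694040241,0.0109345820267879,2.7145846728195293,0.5205992734968086,8.207325921605815,0.8713466447245132,20.974983635545808,0.0,0.0018505111168583253,0.6,0.6,0.0,0.001,1.0,53.94534217496236
Red gurnard,3875.085002681456,1560.7067373157745,0.1655417482499299,0.0103562004702807,3.3140203846660348,0.2363257445785362,25.4540486309803,1.5581707972843777,21.66806031561758,0.0,0.0010080971550109827,0.6,0.6,0.0,0.001,1.0,1.6478681965929873
Red cod,229.2546111845236,20.752479848779217,0.6856348967560152,0.0114387968887951,2.661271779033602,1.0804514371681455,100.0,1.3,34.96909242723733,0.0,0.001822748906750753,0.6,0.6,0.0,0.001,1.0,126.65514419229058
Reef fish invert,777.4303339509821,282.47477847765,0.2904630111624245,0.0098960560825639,2.8015120891478764,0.568887202766469,17.00273750702744,1.159986872513504,22.25683553200661,0.0,0.0014212066068964345,0.6,0.6,0.0,0.001,1.0,231.54426856977304
Reef fish pisc,1042.4143045041935,93.23610358289363,0.2385516898861689,0.0280202415449344,3.408580690707608,0.584906492796653,9.03974129107649,0.5,20.156480627996487,0.0,0.003086060734988897,0.6,0.6,0.0,0.001,1.0,96.78052234000096
Rig,2577.8108513172338,1253.1495646311416,0.1773075572890921,0.0180642111666686,2.9493615021437884,0.2464892997297851,24.305394273580852,1.51378197758073,20.259544797407813,0.0,0.0009726139681142166,0.6,0.6,0.0,0.001,1.0,4.508942237136792
School shark,8037.40307416306,3666.4308282359416,0.0584288828031331,0.0071852074195725,2.8059566241506526,0.1114770850687943,40.86354337791386,1.8649629226746005,9.753300069712097,0.0,0.0003697683414291334,0.6,0.6,0.0,0.001,1.0,111.32784552119058
Snapper,15909.172660180346,5447.793437054191,0.05,0.0105324899707199,2.5416141738618925,0.1077407151341263,46.65487882486958,1.9648902074078425,10.479437134293528,0.0,0.0003744227238754649,0.6,0.6,0.0,0.001,1.0,31.54182785019229
Southern spiny dogfish,5179.590219258592,595.8387447565158,0.0788235623389516,0.0143300056937959,2.6705929685368863,0.2133651246203617,13.083575962568515,1.1605520421906326,11.36510048022105,0.0,0.000734927405730463,0.6,0.6,0.0,0.001,1.0,90.18844422723281
Tarakihi,11335.381632340215,2336.124806628946,0.0792048400285832,0.0052085263438483,3.458559213241445,0.1340477598466501,23.860181437152505,1.6128760490878478,14.826860126137495,0.0,0.0006684294795346215,0.6,0.6,0.0,0.001,1.0,8.282769174469205
Cephalopod,630.2933734183357,54.97954550122239,1.488040429807079,0.0309533026678506,3.437826454974983,2.7785883027523908,5.398616043014852,0.5,106.31986066082261,0.0,0.016703129191869417,0.6,0.6,0.0,0.001,1.0,13.465680136289464
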