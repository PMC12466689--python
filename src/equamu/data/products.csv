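product_id,trade_name,origin,route,authorized_food_horse,substances
EQ001,Trimethosel oral paste,veterinary,oral,true,sulfadiazine:sulfonamides:333mg/g;trimethoprim:sulfonamides:67mg/g
EQ026,Sulfatrim granulate,veterinary,oral,true,sulfamethoxazole:sulfonamides:400mg/g;trimethoprim:sulfonamides:80mg/g
EQ002,Amoxivet powder,veterinary,oral,true,amoxicillin:beta-lactams:500mg/g
EQ003,Ampiject,veterinary,parenteral,true,ampicillin:beta-lactams:150mg/ml
EQ004,Penisol injection,veterinary,parenteral,true,benzylpenicillin:beta-lactams:300000IU/ml
EQ025,Procapen injection,veterinary,parenteral,true,benzylpenicillin:beta-lactams:300mg/ml
EQ009,Clavamox tablets,veterinary,oral,true,amoxicillin:beta-lactams:400mg;clavulanic acid:beta-lactams:100mg
EQ005,Gentaject 10%,veterinary,parenteral,true,gentamicin:aminoglycosides:100mg/ml
EQ006,Gentamicin-Ophtal eye drops,human,topical,true,gentamicin:aminoglycosides:5mg/ml
EQ024,Neomycin-Ophtal eye drops,human,topical,true,neomycin:aminoglycosides:3.5mg/ml
EQ008,Neopolyderm eye ointment,veterinary,topical,false,neomycin:aminoglycosides:3.5mg/g;polymyxin b:polymyxins:6000IU/g
EQ020,Polyspectran B eye drops,human,topical,false,polymyxin b:polymyxins:7500IU/ml
EQ007,Floxal eye drops,human,topical,false,ofloxacin:fluoroquinolones:3mg/ml
EQ010,Enroxil injection,veterinary,parenteral,true,enrofloxacin:fluoroquinolones:100mg/ml
EQ011,Marbogel oral gel,veterinary,oral,true,marbofloxacin:fluoroquinolones:20mg/g
EQ012,Cequin injection,veterinary,parenteral,true,cefquinome:cephalosporins-3/4gen:45mg/ml
EQ014,Ceftio injection,veterinary,parenteral,true,ceftiofur:cephalosporins-3/4gen:50mg/ml
EQ013,Cefovet injection,veterinary,parenteral,false,cefovecin:cephalosporins-3/4gen:80mg/ml
EQ015,Cefadrops,veterinary,oral,true,cefalexin:cephalosporins-1/2gen:50mg/ml
EQ016,Chloramphenicol-Ophtal ointment,human,topical,false,chloramphenicol:amphenicols:10mg/g
EQ017,Clindatab,veterinary,oral,false,clindamycin:lincosamides:150mg
EQ018,Fusiderm eye gel,human,topical,false,fusidic acid:steroid-antibiotics:10mg/g
EQ019,Metrotab,human,oral,false,metronidazole:nitroimidazoles:400mg
EQ021,Oxyvet eye ointment,veterinary,topical,true,oxytetracycline:tetracyclines:10mg/g
EQ022,Doxybene powder,veterinary,oral,true,doxycycline:tetracyclines:500mg/g
EQ023,Erythrovet granulate,veterinary,oral,true,erythromycin:macrolides:200mg/g
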