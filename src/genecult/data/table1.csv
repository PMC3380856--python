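population,subdivision,country,lat,lon,n,n_rr,n_ra,n_aa,printed_freq
Yaqui,mesoamerican_agriculturalist,Mexico,27.483,-110.667,45,30,11,4,0.21
Tarahumara,mesoamerican_agriculturalist,Mexico,26.817,-107.067,109,81,23,5,0.15
Teenek,mesoamerican_agriculturalist,Mexico,21.600,-98.967,67,45,20,2,0.18
Cora,mesoamerican_agriculturalist,Mexico,22.050,-104.917,123,62,51,10,0.29
Purepecha,mesoamerican_agriculturalist,Mexico,19.600,-102.233,35,22,11,2,0.21
Mazahua,mesoamerican_agriculturalist,Mexico,19.433,-100.000,83,68,15,0,0.09
Mixe,mesoamerican_agriculturalist,Mexico,17.000,-96.000,19,15,4,0,0.11
Mixtec,mesoamerican_agriculturalist,Mexico,17.000,-97.000,4,4,0,0,0.00
Nahuatl,mesoamerican_agriculturalist,Mexico,19.967,-97.617,267,185,73,9,0.17
Totonaco,mesoamerican_agriculturalist,Mexico,19.950,-97.733,113,86,24,3,0.13
Otomies,mesoamerican_agriculturalist,Mexico,20.467,-99.217,42,35,7,0,0.08
Zapotec,mesoamerican_agriculturalist,Mexico,17.233,-96.233,125,71,50,4,0.24
Mayan,mesoamerican_agriculturalist,Mexico,20.217,-90.467,110,68,39,3,0.20
Kaqchikel-Quiche,mesoamerican_agriculturalist,Guatemala,15.000,-91.000,17,13,3,1,0.15
Cabecar,mesoamerican_agriculturalist,Costa Rica,9.500,-84.000,24,19,5,0,0.10
Guaymi,mesoamerican_agriculturalist,Costa Rica/Panama,8.500,-82.000,35,26,8,1,0.15
Parkateje (Gaviao),sa_hunter_gatherer,Brazil,-5.050,-48.600,78,65,12,1,0.09
Jamamadi,sa_hunter_gatherer,Brazil,-7.250,-66.683,26,26,0,0,0.00
Mekranoti (Kayapo),sa_hunter_gatherer,Brazil,-8.667,-54.000,25,24,1,0,0.02
Mura (Piraha),sa_hunter_gatherer,Brazil,-3.567,-59.200,18,11,6,1,0.22
Pacaas-Novos (Wari),sa_hunter_gatherer,Brazil,-11.133,-65.083,25,23,2,0,0.04
Satere-Mawe,sa_hunter_gatherer,Brazil,-3.000,-57.000,25,20,4,1,0.12
Apalai,sa_hunter_gatherer,Brazil,1.333,-54.667,22,15,7,0,0.16
Arara,sa_hunter_gatherer,Brazil,-3.500,-54.167,24,15,9,0,0.19
Guarani,sa_hunter_gatherer,Brazil,-25.333,-52.500,31,30,1,0,0.02
Gorotire (Kayapo),sa_hunter_gatherer,Brazil,-7.733,-51.167,7,6,0,1,0.14
Karitiana,sa_hunter_gatherer,Brazil,-8.750,-63.850,20,20,0,0,0.00
Xavante,sa_hunter_gatherer,Brazil,-13.333,-51.667,21,10,9,2,0.31
Xikrin (Kayapo),sa_hunter_gatherer,Brazil,-5.917,-51.183,17,16,1,0,0.03
Yanomama,sa_hunter_gatherer,Brazil,3.500,-64.000,25,20,4,1,0.12
Txukahamae (Kayapo),sa_hunter_gatherer,Brazil,-10.333,-53.083,30,26,4,0,0.07
Tiriyo (Trio),sa_hunter_gatherer,Brazil,1.950,-55.817,25,21,4,0,0.08
Icana River (Baniwa),sa_hunter_gatherer,Brazil,1.000,-67.833,19,13,3,3,0.24
Kuben Kran Keng (Kayapo),sa_hunter_gatherer,Brazil,-8.167,-58.133,17,13,4,0,0.12
Lengua,sa_hunter_gatherer,Paraguay,-23.000,-56.000,29,29,0,0,0.00
Ache (Guayaki),sa_hunter_gatherer,Paraguay,-23.000,-58.000,23,23,0,0,0.00
Ayoreo,sa_hunter_gatherer,Paraguay,-19.000,-60.500,30,30,0,0,0.00
Zenu,sa_hunter_gatherer,Colombia,9.000,-75.000,4,4,0,0,0.00
Kogi,sa_hunter_gatherer,Colombia,11.000,-74.000,7,7,0,0,0.00
Ticuna,sa_hunter_gatherer,Colombia,-3.883,-70.000,1,1,0,0,0.00
Embera,sa_hunter_gatherer,Colombia,7.000,-76.000,3,3,0,0,0.00
Wayuu,sa_hunter_gatherer,Colombia,11.000,-73.000,17,15,2,0,0.06
Palikur,sa_hunter_gatherer,French Guiana,4.000,-51.750,3,1,2,0,0.33
Mapuche,andean_agriculturalist,Chile,-40.500,-69.333,40,40,0,0,0.00
Aymara (Bolivia),andean_agriculturalist,Bolivia,-16.500,-68.150,16,16,0,0,0.00
Quechua,andean_agriculturalist,Bolivia,-14.500,-69.000,16,15,1,0,0.03
Aymara (Chile),andean_agriculturalist,Chile,-22.000,-70.000,22,20,2,0,0.05
Chilote,andean_agriculturalist,Chile,-42.500,-73.917,2,2,0,0,0.00
Hulliche,andean_agriculturalist,Chile,-41.000,-73.000,13,10,3,0,0.11
Ingano,andean_agriculturalist,Colombia,1.000,-77.000,6,5,1,0,0.08
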