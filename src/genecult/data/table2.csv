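population,site,region,radiocarbon_bp,calendar_bp,frequency
Zapotec,Guila Naquitz,Oaxaca,8240,9212,0.24
Maya,San Andres,Tabasco,6208,7122,0.20
Nahuatl,Zoalpilco,Mexico state,5090,5835,0.17
Kaqchikel-Quiche,Zipacate,Guatemala,4600,5318,0.15
Totonac,Laguna Pompal,Veracruz,4250,4818,0.13
Cabecar,Lago Cote,Costa Rica,2940,3096,0.10
Guaymi,Gatun Lake,Panama,4000,4468,0.15
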