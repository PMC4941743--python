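tribe,taxon,n_D,mean_D,sd_D,n_area,mean_area,sd_area
Equini,Calippus placidus,2,1.5180,0.0891,2,2.0815,0.0629
Equini,Calippus sp.,1,1.3580,,1,3.6030,
Equini,Equus asinus,1,1.2290,,1,5.1590,
Equini,Equus caballus,4,1.4373,0.0549,4,7.5205,1.6367
Equini,Equus calobutus,4,1.3223,0.0714,4,7.2530,1.9051
Equini,Equus complicatus,1,1.4050,,1,6.0810,
Equini,Equus conversidens,1,1.3270,,1,5.3290,
Equini,Equus excelsus,4,1.3810,0.0879,3,6.6210,1.1453
Equini,Equus fraternus,1,1.3030,,1,8.7110,
Equini,Equus grevyi,1,1.2760,,1,7.5950,
Equini,Equus idahoensis,6,1.3293,0.0418,5,6.5108,0.7770
Equini,Equus occidentalis,1,1.4240,,1,8.2630,
Equini,Equus quagga,4,1.2483,0.0176,4,5.6980,0.4205
Equini,Equus scotti,7,1.3453,0.0598,7,6.8604,1.7839
Equini,Equus simplicidens,13,1.3949,0.0330,9,7.8007,1.6641
Equini,Equus sp.,5,1.3266,0.0221,5,5.2488,0.5808
Equini,Equus spp.,4,1.3075,0.0076,4,6.0648,0.5734
Equini,Pliohippus mirabilis,1,1.4010,,0,,
Equini,Pliohippus pernix,1,1.4000,,1,3.8970,
Equini,Pliohippus sp.,1,1.3980,,1,5.2170,
Equini,Protohippus perditus,2,1.3870,0.0170,2,3.3080,0.0198
Equini,Protohippus sp.,2,1.3880,0.0523,2,3.0135,0.5211
Hipparionini,Cormohipparion goorisi,1,1.4150,,1,3.8000,
Hipparionini,Cormohipparion ingenuus,1,1.3170,,1,3.1690,
Hipparionini,Cormohipparion occidentale,4,1.3493,0.0326,4,4.3823,1.3176
Hipparionini,Cormohipparion quinni,1,1.4450,,1,4.5870,
Hipparionini,Cormohipparion sphenodus,1,1.4270,,1,5.3150,
Hipparionini,Neohipparion affine,5,1.4334,0.0821,5,3.6038,0.9205
Hipparionini,Neohipparion eurystyle,2,1.3520,0.0764,2,4.0775,0.0700
Hipparionini,Neohipparion leptode,1,1.4200,,1,4.2290,
Hipparionini,Neohipparion republicanus,3,1.4593,0.0577,3,3.4333,0.4258
Hipparionini,Neohipparion sp.,5,1.4622,0.0905,5,3.9066,0.7120
Hipparionini,Pseudhipparion gratum,2,1.3715,0.0445,0,,
Hipparionini,Pseudhipparion sp.,4,1.4600,0.1061,4,3.3113,0.3720
Hipparionini,gen. et sp. indet.,1,1.4850,,1,3.0090,
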