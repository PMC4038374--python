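species,clade,n,body_mass_g,hindlimb_length_cm,thigh_mass_g,shank_mass_g,pes_mass_g,tars_mass_g,digit_mass_g
Falco tinnunculus,Land birds,1,170.0,15.9,3.92,5.52,2.45,--,--
Falco peregrinus,Land birds,1,425.9,20.7,10.60,10.90,5.60,2.60,2.90
Corvus corone,Land birds,1,575.0,19.4,18.91,18.11,6.58,2.91,3.61
Corvus brachyrhynchos,Land birds,1,402.0,--,12.80,14.70,4.60,2.10,2.50
Pica pica,Land birds,1,195.0,15.2,7.08,7.47,1.68,0.88,0.80
Corvus monedula,Land birds,1,255.0,17.1,6.50,7.71,2.40,1.23,1.16
Accipiter nisus,Land birds,1,260.0,19.7,7.15,9.15,3.07,1.80,1.26
Accipiter striatus,Land birds,1,111.6,16.0,3.00,3.90,2.20,1.20,0.90
Buteo buteo,Land birds,2,780.0,25.1,30.88,37.81,15.16,8.71,6.42
Buteo jamaicensis,Land birds,2,2185.0,30.7,46.10,51.05,20.75,11.50,9.15
Bubo virginianus,Land birds,1,1028.0,30.6,44.20,59.60,25.30,12.30,13.00
Tyto alba,Land birds,1,218.0,19.1,8.41,12.18,4.87,2.58,2.29
Lanius collurio,Land birds,1,30.0,7.9,0.75,0.73,0.20,0.09,0.11
Turdus merula,Land birds,2,97.5,11.1,2.50,2.43,0.59,0.27,0.32
Turdus philomelos,Land birds,2,69.0,10.0,1.87,1.54,0.36,0.18,0.18
Alauda arvensis,Land birds,1,40.0,--,0.88,0.77,0.20,0.08,0.11
Fringilla coelebs,Land birds,1,18.0,6.1,0.30,0.24,0.09,0.04,0.05
Pyrrhula pyrrhula,Land birds,1,28.0,6.5,0.44,0.36,0.13,0.06,0.07
Cardinalis cardinalis,Land birds,2,34.5,--,0.55,0.57,0.29,0.14,0.15
Cathurus guttatus,Land birds,1,29.5,9.7,0.53,0.66,0.21,0.11,0.10
Zonotrichia albicollis,Land birds,1,28.2,8.7,0.60,0.52,0.23,0.104,0.12
Alcedo atthis,Land birds,1,33.0,5.6,0.41,0.21,0.12,0.05,0.06
Picus viridis,Land birds,1,205.0,12.2,5.61,3.75,1.19,0.53,0.66
Colaptes auratus,Land birds,1,135.4,9.8,3.40,2.30,0.90,0.40,0.50
Vanellus vanellus,Charadriiformes,1,178.0,15.9,5.14,4.03,1.58,0.87,0.69
Recurvirostra avosetta,Charadriiformes,1,195.0,23.3,5.20,7.30,4.44,2.57,1.81
Haematopus ostralegus,Charadriiformes,1,433.3,20.1,15.74,10.96,4.69,--,--
Scolopax minor,Charadriiformes,2,162.4,13.1,6.45,3.70,1.09,0.55,0.50
Pygoscelis adeliae,Water Birds,1,4030.0,25.4,138.75,77.45,30.5,11.65,18.65
Ardea herodias,Water Birds,1,2300.0,45.9,31.70,43.00,18.10,13.00,5.00
Rallus aquaticus,Core Gruiformes,1,83.0,13.7,4.34,3.30,1.10,0.57,0.53
Gallinula chloropus,Core Gruiformes,1,380.0,19.5,21.45,13.14,4.47,2.00,2.44
Bonasa umbellus,Galloanseraes,1,564.9,20.08,21.05,13.65,3.15,1.35,1.75
Coturnix coturnix,Galloanseraes,1,205.0,15.2,9.39,6.84,1.87,0.87,0.96
Pavo cristatus,Galloanseraes,1,2775.0,39.8,154.17,134.52,47.61,28.10,19.41
Branta canadensis,Galloanseraes,1,6975.0,36.0,108.20,109.40,22.10,13.60,8.40
Apus apus,Apodiformes,2,40.0,4.9,0.83,0.70,0.17,0.08,0.09
Columba livia,Columbiformes,2,322.5,14.5,7.14,5.32,2.04,1.02,1.03
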