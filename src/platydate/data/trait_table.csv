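genus,clade,body_mass_g,generation_time_yr,is_fossil
Alouatta,Atelidae,6404.2,12.0,0
Ateles,Atelidae,8276.3,15.0,0
Brachyteles,Atelidae,8840.0,20.0,0
Lagothrix,Atelidae,7150.0,15.0,0
Aotus,Aotinae,1018.7,8.0,0
Cebus,Cebinae,2475.1,15.0,0
Saimiri,Cebinae,786.9,8.0,0
Saguinus,Callitrichinae,444.4,6.0,0
Leontopithecus,Callitrichinae,471.4,7.0,0
Callithrix,Callitrichinae,351.2,6.0,0
Callimico,Callitrichinae,505.0,6.0,0
Callicebus,Pitheciidae,997.3,8.0,0
Pithecia,Pitheciidae,2003.5,9.0,0
Cacajao,Pitheciidae,2893.8,10.0,0
Chiropotes,Pitheciidae,2632.5,10.0,0
Soriacebus,Pitheciidae,2000.0,9.0,1
Carlocebus,Pitheciidae,2000.0,9.0,1
Homunculus,Pitheciidae,2700.0,10.0,1
Cebupithecia,Pitheciidae,2200.0,9.0,1
Nuciruptor,Pitheciidae,2000.0,9.0,1
Proteropithecia,Pitheciidae,1600.0,9.0,1
Tremacebus,Aotinae,1800.0,9.0,1
Aotus_dindensis,Aotinae,1000.0,8.0,1
Dolichocebus,Cebinae,2700.0,10.0,1
Chilecebus,Cebinae,1000.0,8.0,1
Neosaimiri,Cebinae,840.0,8.0,1
Laventiana,Cebinae,800.0,8.0,1
Stirtonia,Atelidae,5800.0,12.0,1
Stirtonia_major,Atelidae,10000.0,20.0,1
Protopithecus,Atelidae,23500.0,22.0,1
Caipora,Atelidae,24000.0,22.0,1
Patasola,Callitrichinae,1000.0,8.0,1
Lagonimico,Callitrichinae,1300.0,8.0,1
Branisella,Incertae_sedis,1000.0,8.0,1
Szalatavus,Incertae_sedis,550.0,7.0,1
Homo,Hominidae,45000.0,29.0,0
Pan,Hominidae,33000.0,25.0,0
Gorilla,Hominidae,71000.0,19.0,0
Macaca,Cercopithecinae,9000.0,10.0,0
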