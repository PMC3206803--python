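class,common_name,coral_reef,kelp_forest,mangrove_forest,seagrass_bed,total_printed
Actinopterygii,Ray-finned fishes,1256,29,31,243,1559
Anthozoa,"Anemones, corals",994,7,2,11,1014
Liliopsida,Seagrasses,45,2,26,553,626
Malacostraca,"Crabs, lobsters, shrimp, krill, amphipods, isopods",233,29,90,236,588
Magnoliopsida,Mangroves,34,0,350,17,401
Phaeophyceae,Brown algae (including kelp),145,122,3,28,298
Gastropoda,"Snails, slugs",102,26,50,47,225
Echinoidea,"Sea urchins, sand dollars",115,34,2,39,190
Demospongiae,Sponges,159,0,6,24,189
Bivalvia,Bivalves,86,2,18,79,185
Florideophyceae,Red algae,124,9,4,33,170
Polychaeta,Segmented worms,68,5,11,49,133
Hydrozoa,Hydrozoans,109,3,4,4,120
Bryopsidophyceae,Green algae,57,2,0,41,100
Asteroidea,Starfish,78,2,1,11,92
Ulvophyceae,Green algae (sea lettuce),46,2,3,31,82
Gymnolaemata,Moss animals,77,1,0,2,80
Maxillopoda,"Barnacles, copepods",40,2,12,23,77
Mammalia,Mammals,15,12,7,27,61
Ascidiacea,Sea squirts,30,2,0,5,37
Insecta,Insects,0,0,32,1,33
Holothuroidea,Sea cucumbers,20,0,0,13,33
Aves,Birds,4,2,15,10,31
Reptilia,"Reptiles (sea snakes, turtles, crocodiles)",22,0,2,7,31
Tentaculata,Comb jellies (with tentacles),29,0,0,0,29
Elasmobranchii,"Sharks, rays, skates",22,0,1,5,28
Trematoda,Flukes,27,0,1,0,28
Monogenea,Ectoparasitic flatworms,20,0,1,1,22
Adenophorea,Roundworms,8,0,7,3,18
Scyphozoa,True jellyfish,16,0,0,0,16
Ophiuroidea,Brittle stars and basket stars,15,0,0,1,16
Thaliacea,Salps and relatives,1,0,0,12,13
Bacillariophyceae,Pennate diatoms,4,0,3,4,11
Ostracoda,Seed shrimp,5,0,2,4,11
Chlorophyceae,Green algae,6,1,1,2,10
Crinoidea,"Sea lilies, feather stars",6,0,4,0,10
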