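group,taxon,common_name,range_class,dens_1931_1933,dens_1993_1996,sd_1993_1996,dens_1999_2015,sd_1999_2015,dens_2016_2019,sd_2016_2019,dens_2020_2023,sd_2020_2023,lrr,lrr_lo,lrr_hi
Anthozoans,Anthopleura sola,Anemone,S,0,4.7,0.3,4.7,0.7,4.9,0.2,4.1,1.1,4.7,4.6,4.7
Anthozoans,Anthopleura xanthogrammica,Anemone,C,1.1,0.2,0,0,0,0,0,0,0.1,-2.8,-3.1,-2.5
Anthozoans,Corynactis californica,Anemone,C,0,5.9,0.1,4.6,4.2,0,0,0,0,2.4,1.3,3.5
Bivalves,Mytilus californianus,Mussel,C,9.3,0.3,0.2,0.2,0.1,3.2,2.7,87.2,88.6,-2,-3.1,-0.9
Crustaceans,Balanus glandula,Barnacle,C,0,121.3,167.1,0.3,0.5,0.9,0.7,0,0,1.8,0.7,3
Crustaceans,Chthamalus dalli/fissus,Barnacle,U,0,254.1,63.8,122.6,189.3,2.3,3,129.8,250.8,5.1,3.5,6.7
Crustaceans,Pachycheles rudis,Crab,C,8.5,0,0,0,0,0,0,0.3,0.5,-5,-5.4,-4.6
Crustaceans,Pachygrapsus crassipes,Crab,C,2.1,0.9,0.2,0.3,0.3,0.6,0.4,0.9,0.1,-1.5,-2,-1.1
Crustaceans,Petrolisthes cinctipes,Crab,C,3.7,0,0,0,0.1,0.1,0.1,0.6,0.3,-3.6,-4.1,-3.1
Crustaceans,Pugettia producta,Crab,C,1.8,0.5,0.2,0.2,0.1,0.2,0.1,0.2,0.2,-2.2,-2.5,-1.8
Crustaceans,Pugettia richii,Crab,C,0,0.3,0.4,0.1,0.1,0,0.1,0.1,0.1,0.9,0.5,1.2
Crustaceans,Tetraclita rubescens,Barnacle,S,0,22.3,23.4,6.6,10.2,8.4,15,0,0.1,3.4,2.3,4.4
Echinoderms,Amphipholis squamata,Brittle star,C,4.1,0,0,0,0,0,0,0,0,-4.5,-4.6,-4.4
Echinoderms,Leptasterias spp.,Sea star,U,1.9,0.8,0.3,0.1,0.1,0.1,0,0.2,0.1,-2.3,-2.6,-1.9
Echinoderms,Patiria miniata,Sea star,C,0,0.3,0,0,0,0.1,0.1,0,0,0.7,0.3,1
Echinoderms,Pisaster ochraceus,Sea star,C,0.7,0,0,0,0.1,0,0,0,0,-2.5,-2.8,-2.3
Echinoderms,Strongylocentrotus purpuratus,Sea urchin,C,11.3,1.3,0.5,0.6,0.7,0.9,0.9,7.1,5.6,-2.4,-3,-1.8
Gastropods,Acanthinucella punctulata,Snail,S,0,0.5,0.5,0.2,0.1,0.2,0.2,0.8,0.5,1.8,1.4,2.3
Gastropods,Acmaea mitra,Limpet,C,0.6,0.1,0.1,0.1,0.1,0.2,0.1,0.2,0.4,-1.7,-2.2,-1.3
Gastropods,Alia carinata,Snail,C,122.4,5,1.6,0.8,0.5,0.6,0.8,0.9,1.1,-5.1,-5.6,-4.6
Gastropods,Amphissa versicolor,Snail,C,9.1,2.2,1.5,0.2,0.1,0.6,0.5,3,3.5,-2.7,-3.2,-2.2
Gastropods,Californiconus californicus,Snail,S,0,0,0,0,0,0.1,0.1,0.5,0.4,0.7,0.2,1.2
Gastropods,Calliostoma ligatum,Snail,C,0.5,1.2,0.5,1,0.6,0.9,0.4,0.4,0.3,0.4,0.1,0.7
Gastropods,Crepidula adunca,Snail,C,11.3,19.5,5.4,19.6,6.9,22.1,10.5,20.6,6.5,0.5,0.3,0.7
Gastropods,Epitonium tinctum,Snail,C,0,0.2,0,0,0,0,0.1,0.1,0.1,0.6,0.3,0.9
Gastropods,Fissurella volcano,Keyhole limpet,S,0.7,1.7,0.5,0.4,0.2,0.5,0.3,0.4,0.4,-0.4,-0.7,-0.1
Gastropods,Hesperaptyxis luteopictus,Snail,S,0,0.1,0,0.1,0.2,0,0,0,0,0.5,0.2,0.8
Gastropods,Lacuna marmorata,Snail,C,0,3.5,1.6,1.5,1.4,0,0,0,0,1.8,0.9,2.7
Gastropods,Littorina plena/scutulata,Snail,C,0,0.3,0.3,0.1,0.2,0.1,0.1,0.4,0.2,0.5,-0.1,1
Gastropods,Lottia instabilis,Limpet,C,0,0,0,0,0,1.1,1,0,0,0.6,0,1.3
Gastropods,Lottia limatula,Limpet,C,5.5,1.5,0.7,0.3,0.3,3.5,3.2,1,0.4,-2.1,-2.6,-1.5
Gastropods,Lottia scabra,Limpet,C,0.1,1.7,1.6,2.9,6,1.4,2.4,0.4,0.6,1.1,0.4,1.9
Gastropods,Lottia scutum,Limpet,C,33.1,0.2,0.2,0.2,0.1,0,0,0.1,0.1,-5.6,-5.9,-5.3
Gastropods,Paciocinebrina circumtexta,Snail,C,0,1,0.2,0.5,0.3,0.7,0.2,2.2,0.6,2.9,2.6,3.2
Gastropods,Tectura paleacea,Limpet,C,0,0.7,0.1,0.1,0.1,0,0,0,0,0.6,0.1,1.1
Gastropods,Tegula brunnea,Snail,C,0.1,30.6,6,7.5,4.3,9.1,3,8,5.4,3.9,3.5,4.2
Gastropods,Tegula funebralis,Snail,C,47.1,150.5,8.2,124.5,40.4,271.7,32.7,286.5,29.3,1.3,1.1,1.6
Gastropods,Tegula pulligo,Snail,C,0,0.5,0.7,0,0,0,0,0.1,0.1,0.4,0,0.8
Gastropods,Thylacodes squamigerus,Snail,S,0,10.9,5,7.5,5.1,1.6,1,1.2,0.9,4.2,3.7,4.8
Platyhelminths,Notocomplana acticola,Flatworm,C,0,0,0,0,0,0,0,0.2,0.3,0.3,-0.1,0.7
Polychaetes,Halosydna brevisetosa,Segmented worm,C,4,0,0,0,0,0,0,0.1,0.2,-4.3,-4.6,-4
Polyplacophorans,Mopalia muscosa,Chiton,C,0.6,0.3,0.1,0,0,0.1,0.1,0.4,0.3,-1.4,-1.8,-1
Polyplacophorans,Nuttallina californica,Chiton,C,0,0.1,0.2,0.2,0.2,0.1,0.2,0.1,0.1,1.2,0.7,1.6
Polyplacophorans,Tonicella lineata,Chiton,C,0,0.1,0,0,0,0.1,0.1,0.1,0.1,0.2,-0.1,0.4
Poriferans,Haliclona sp. A,Sponge,S,0,0,0,0,0,0,0,0.5,0.4,0.5,0,1
Sipunculids,Phascolosoma agassizii,Peanut worm,C,3.7,0,0,0,0,0,0,0.1,0.2,-4.3,-4.6,-4
Tunicates,Clavelina huntsmani,Sea squirt,C,17.3,12.4,4.8,3.9,4.1,16.6,9.8,31.8,50.6,-1.5,-2.5,-0.4
Tunicates,Polyclinum planum,Sea squirt,S,0.1,0.2,0.2,0.1,0.1,0.2,0.3,0.1,0.3,-0.1,-0.6,0.3
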