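scientific_name,common_name,label,ecotype
Gadus morhua,Atlantic cod,cod,marine
Clupea harengus,Atlantic herring,herring,marine
Sprattus sprattus,European sprat,sprat,marine
Merlangius merlangus,Whiting,whiting,marine
Scophthalmus maximus,Turbot,turbot,marine
Scophthalmus rhombus,Brill,brill,marine
Limanda limanda,Common dab,dab,marine
Platichthys flesus,European flounder,flounder,marine
Pleuronectes platessa,European plaice,plaice,marine
Solea solea,Common sole,sole,marine
Scomber scombrus,Atlantic mackerel,mackerel,marine
Chelon labrosus,Thicklip grey mullet,mullet,marine
Belone belone,Garfish,garfish,marine
Cyclopterus lumpus,Lumpsucker,lumpsucker,marine
Zoarces viviparus,Eelpout,eelpout,marine
Salmo salar,Atlantic salmon,salmon,anadromous
Salmo trutta,Sea trout,trout,anadromous
Anguilla anguilla,European eel,eel,catadromous
Perca fluviatilis,European perch,perch,freshwater-brackish
Sander lucioperca,Pikeperch,pikeperch,freshwater-brackish
Esox lucius,Northern pike,pike,freshwater-brackish
Neogobius melanostomus,Round goby,goby,freshwater-brackish
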