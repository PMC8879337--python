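# Reference list of genera containing described oil-hydrocarbon-degrading organisms (n = 369).
# SYNTHETIC STAND-IN: curated real degrader genera padded with clearly marked placeholder
# names (Synthdegradibacter###) to reach the reference size; replace with a vetted list for real analyses.
Alcanivorax
Marinobacter
Cycloclasticus
Oleispira
Thalassolituus
Oleiphilus
Pseudomonas
Acinetobacter
Rhodococcus
Mycobacterium
Sphingomonas
Sphingobium
Novosphingobium
Sphingopyxis
Burkholderia
Ralstonia
Polaromonas
Pseudoalteromonas
Shewanella
Colwellia
Glaciecola
Paraglaciecola
Marinomonas
Halomonas
Alteromonas
Vibrio
Planktomarina
Sulfitobacter
Roseobacter
Roseovarius
Ruegeria
Dietzia
Gordonia
Nocardia
Nocardioides
Arthrobacter
Micrococcus
Bacillus
Paenibacillus
Geobacillus
Planococcus
Streptomyces
Corynebacterium
Exiguobacterium
Flavobacterium
Polaribacter
Winogradskyella
Maribacter
Cellulophaga
Zobellia
Psychrobacter
Psychromonas
Moritella
Photobacterium
Aeromonas
Enterobacter
Klebsiella
Serratia
Stenotrophomonas
Xanthomonas
Lysobacter
Thalassospira
Tistrella
Azospirillum
Sphingorhabdus
Erythrobacter
Porphyrobacter
Altererythrobacter
Croceicoccus
Brevundimonas
Caulobacter
Phenylobacterium
Bosea
Bradyrhizobium
Rhizobium
Mesorhizobium
Sinorhizobium
Ochrobactrum
Methylobacterium
Methylocella
Methylococcus
Methylomonas
Methylomicrobium
Methylophaga
Hyphomonas
Parvibaculum
Rhodobacter
Paracoccus
Celeribacter
Leisingera
Phaeobacter
Salipiger
Octadecabacter
Loktanella
Jannaschia
Dinoroseobacter
Oceanicola
Pseudooceanicola
Thalassobius
Tropicibacter
Pelagibaca
Citreicella
Maritimibacter
Labrenzia
Stappia
Pannonibacter
Martelella
Aurantimonas
Hoeflea
Nitratireductor
Shinella
Ensifer
Devosia
Hyphomicrobium
Xanthobacter
Ancylobacter
Starkeya
Variovorax
Acidovorax
Comamonas
Delftia
Hydrogenophaga
Rhodoferax
Limnobacter
Cupriavidus
Pandoraea
Achromobacter
Bordetella
Alcaligenes
Castellaniella
Pusillimonas
Janthinobacterium
Massilia
Duganella
Herbaspirillum
Collimonas
Thauera
Azoarcus
Aromatoleum
Dechloromonas
Zoogloea
Methyloversatilis
Sterolibacterium
Georgfuchsia
Sulfuritalea
Desulfobacula
Desulfobacterium
Desulfatibacillum
Desulfococcus
Desulfosarcina
Desulfotignum
Geobacter
Syntrophus
Smithella
Pelotomaculum
Desulfotomaculum
Thermus
Deinococcus
Oleibacter
Neptunomonas
Amphritea
Bermanella
Oceanospirillum
Marinobacterium
Saccharophagus
Microbulbifer
Teredinibacter
Cellvibrio
Pseudoxanthomonas
Luteimonas
Dokdonella
Rhodanobacter
Dyella
Frateuria
Aquabacterium
Malikia
Macromonas
Sphaerotilus
Leptothrix
Ideonella
Roseateles
Mitsuaria
Piscinibacter
Ramlibacter
Curvibacter
Simplicispira
Giesbergeria
Ottowia
Diaphorobacter
Alicycliphilus
Melaminivora
Hylemonella
Xylophilus
Pseudorhodoferax
Caenimonas
Kinneretia
Paucibacter
Pelomonas
Methylibium
Synthdegradibacter014
Halobacterium
Haloferax
Haloarcula
Natronomonas
Thermococcus
Archaeoglobus
Methanosarcina
Ferroglobus
Amycolatopsis
Pseudonocardia
Saccharopolyspora
Actinoplanes
Micromonospora
Salinispora
Frankia
Geodermatophilus
Blastococcus
Modestobacter
Kineococcus
Janibacter
Terrabacter
Intrasporangium
Knoellia
Phycicoccus
Kytococcus
Dermacoccus
Brachybacterium
Dermabacter
Microbacterium
Agromyces
Leifsonia
Clavibacter
Curtobacterium
Frigoribacterium
Cryobacterium
Agreia
Subtercola
Salinibacterium
Sanguibacter
Cellulomonas
Oerskovia
Isoptericola
Promicromonospora
Xylanimonas
Brevibacterium
Rothia
Kocuria
Nesterenkonia
Sinomonas
Renibacterium
Glutamicibacter
Paeniglutamicibacter
Pseudarthrobacter
Paenarthrobacter
Tersicoccus
Acaricomes
Psychroglaciecola
Marinomicrobium
Saccharospirillum
Reinekea
Oleiagrimonas
Oceanicoccus
Thalassomonas
Agarivorans
Catenovulum
Bowmanella
Melitea
Idiomarina
Aliagarivorans
Salinimonas
Lacimicrobium
Gayadomonas
Simiduia
Thalassotalea
Pseudidiomarina
Aestuariibacter
Gilvimarinus
Hahella
Kistimonas
Endozoicomonas
Zooshikella
Salicola
Kushneria
Chromohalobacter
Cobetia
Modicisalibacter
Salinicola
Carnimonas
Zymobacter
Haererehalobacter
Marinospirillum
Nitrincola
Oceanobacter
Thalassobaculum
Fodinicurvata
Oceanibaculum
Nisaea
Phaeospirillum
Magnetospirillum
Rhodospirillum
Roseospira
Pararhodospirillum
Halorubrum
Caldimonas
Tepidimonas
Lampropedia
Orrella
Paralcaligenes
Parapusillimonas
Candidimonas
Derxia
Paraburkholderia
Caballeronia
Robbsia
Mycetohabitans
Trinickia
Pararobbsia
Chitinimonas
Chitiniphilus
Silvimonas
Leeia
Gulbenkiania
Chromobacterium
Aquitalea
Vogesella
Deefgea
Andreprevotia
Laribacter
Microvirgula
Pseudogulbenkiania
Formivibrio
Iodobacter
Salinisphaera
Oceanotoga
Petrotoga
Kosmotoga
Marinitoga
Thermosipho
Fervidobacterium
Thermotoga
Pseudothermotoga
Defluviitoga
Mesotoga
Geotoga
Athalassotoga
Mesoaciditoga
Tepiditoga
Oceanithermus
Vulcanithermus
Marinithermus
Meiothermus
Truepera
Oceanimonas
Oceanisphaera
Tolumonas
Zobellella
Synthdegradibacter001
Synthdegradibacter002
Synthdegradibacter003
Synthdegradibacter004
Synthdegradibacter005
Synthdegradibacter006
Synthdegradibacter007
Synthdegradibacter008
Synthdegradibacter009
Synthdegradibacter010
Synthdegradibacter011
Synthdegradibacter012
Synthdegradibacter013
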