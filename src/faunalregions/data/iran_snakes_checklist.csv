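taxon,Sa,O,W,Tu,Ar,Ir,Ce,Ca,A,M,R,Z,WZ,Kh,T,K,S,B,I
Myriopholis blanfordii,0,1,1,0,0,1,0,0,0,0,0,1,0,1,0,0,1,0,0
Myriopholis hamulirostris,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Myriopholis macrorhyncha,1,0,1,0,1,1,0,0,1,0,0,1,1,1,0,0,0,1,0
Indotyphlops braminus,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,1
Xerotyphlops luristanicus,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Xerotyphlops vermicularis,0,0,1,1,0,1,1,1,1,1,1,1,1,1,1,1,0,0,0
Eryx elegans,0,0,1,1,0,1,1,0,1,0,0,0,0,0,0,1,0,0,0
Eryx jayakari,0,0,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Eryx miliaris,0,0,0,1,0,1,1,0,1,0,0,0,0,0,1,1,1,1,0
Eryx sistanensis,0,0,0,0,0,1,0,0,0,0,0,0,0,1,0,0,1,1,0
Eryx sp.,1,0,1,0,0,0,0,0,1,1,1,1,1,1,0,0,0,0,0
Boiga trigonata melanocephala,0,0,1,1,0,1,1,0,0,0,0,0,0,0,1,1,1,1,0
Coronella austriaca,0,0,1,1,0,0,0,1,1,1,1,0,0,0,1,0,0,0,0
Dolichophis andreanus,0,0,1,0,0,1,0,0,0,0,0,1,1,1,0,0,0,0,0
Dolichophis jugularis,0,0,1,1,0,0,0,1,1,0,1,1,1,0,1,1,0,0,0
Dolichophis schmidti,0,0,1,1,0,0,0,1,1,1,1,1,1,0,1,1,0,0,0
Eirenis collaris,0,0,1,0,0,0,0,0,1,1,1,1,1,0,0,0,0,0,0
Eirenis coronella,0,0,0,0,1,0,0,0,0,0,0,0,1,1,0,0,0,0,0
Eirenis coronelloides,0,0,0,0,1,0,0,0,0,0,0,0,1,1,0,0,0,0,0
Eirenis kermanensis,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0
Eirenis medus,0,0,1,0,0,1,0,0,1,0,0,1,0,0,0,1,0,0,0
Eirenis modestus,0,0,1,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0
Eirenis nigrofasciatus,0,0,1,0,0,0,0,0,0,0,0,1,1,1,0,0,0,0,1
Eirenis occidentalis,0,0,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0
Eirenis persicus,0,0,1,0,0,0,0,0,1,0,0,1,1,1,0,0,0,0,1
Eirenis cf. persicus,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
Eirenis punctatolineatus,0,0,1,0,0,1,1,0,1,1,1,1,1,0,0,1,0,0,0
Eirenis punctatolineatus condoni,0,0,1,0,0,1,1,0,0,0,0,0,1,1,0,0,0,0,0
Eirenis rafsanjanicus,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0
Eirenis rechingeri,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Eirenis thospitis,0,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
Eirenis walteri,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,1,1,1,0
Eirenis yassujicus,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Elaphe dione,0,0,1,1,0,0,0,1,1,1,0,0,0,0,1,0,0,0,0
Elaphe urartica,0,0,1,0,0,0,0,1,1,1,1,1,1,0,0,0,0,0,0
Hemorrhois nummifer,0,0,1,1,0,0,0,1,1,1,1,1,1,0,1,1,0,0,0
Hemorrhois ravergieri,0,0,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,0
Lycodon bicolor,0,1,0,1,0,1,0,0,0,0,0,0,0,0,1,1,1,1,0
Lytorhynchus gaddi,1,0,0,0,1,0,0,0,0,0,0,0,1,1,0,0,0,0,1
Lytorhynchus maynardi,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1,1,0
Lytorhynchus ridgewayi,0,0,1,1,1,1,1,0,1,0,0,1,0,1,1,1,1,1,0
Oligodon transcaspicus,0,0,1,1,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0
Persiophis fahimii,0,0,0,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0
Platyceps atayevi,0,0,1,1,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0
Platyceps karelini,0,0,1,1,0,1,1,0,1,0,0,1,0,0,1,1,1,1,0
Platyceps karelini chesneii,1,0,1,0,1,0,0,0,0,0,0,1,1,1,0,0,0,0,1
Platyceps mintonorum,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1,1,0
Platyceps najadum,0,0,1,0,0,0,0,1,1,1,1,0,0,0,0,0,0,0,0
Platyceps najadum albitemporalis,0,0,1,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0
Platyceps rhodorachis,0,0,1,1,1,1,1,0,1,0,0,1,1,1,1,1,1,1,1
Platyceps cf. r. rhodorachis,0,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
Platyceps schmidtleri,0,0,1,0,0,1,0,0,0,0,0,1,1,1,0,0,1,1,0
Platyceps ventromaculatus,0,1,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,1,0
Rhynchocalamus levitoni,0,0,1,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
Rhynchocalamus satunini,0,0,1,0,0,0,0,0,1,0,1,1,1,1,0,0,0,0,0
Spalerosophis diadema cliffordii,1,0,0,0,1,0,0,0,0,0,0,0,1,1,0,0,0,0,1
Spalerosophis schirasianus,0,0,1,1,0,1,1,0,1,0,0,1,0,0,1,1,1,1,1
Spalerosophis microlepis,0,0,1,0,0,0,1,0,0,0,0,1,1,0,0,0,0,0,0
Telescopus fallax iberus,0,0,1,0,0,0,0,1,1,1,1,1,1,0,0,0,0,0,0
Telescopus nigriceps,0,0,1,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,0
Telescopus rhinopoma,0,0,0,0,0,1,1,0,1,0,0,1,0,0,0,1,1,1,1
Telescopus tessellatus tessellatus,0,0,1,0,0,0,1,0,1,0,0,1,1,0,0,0,0,0,0
Telescopus tessellatus martini,0,0,1,0,1,0,0,0,0,0,0,1,1,1,0,0,0,0,0
Zamenis hohenackeri,0,0,1,0,0,0,0,0,1,1,1,1,0,0,0,0,0,0,0
Zamenis longissimus,0,0,1,0,0,0,0,1,1,1,1,1,0,0,0,0,0,0,0
Zamenis persicus,0,0,1,0,0,0,0,1,1,1,0,0,0,0,1,1,0,0,0
Natrix natrix scutata,0,0,1,0,0,0,0,1,1,1,1,0,0,0,1,0,0,0,0
Natrix tessellata,0,0,1,1,1,0,0,1,1,1,1,1,1,1,1,1,0,0,0
Malpolon insignitus fuscus,1,0,1,0,0,0,0,0,1,1,1,1,1,1,0,1,0,0,0
Psammophis lineolatus,0,0,1,1,1,1,1,0,1,0,0,1,1,1,1,1,1,1,0
Psammophis schokari,1,0,1,0,1,1,1,0,1,0,0,1,1,1,1,1,1,1,0
Rhagerhis moilensis,1,0,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,1
Bungarus persicus,0,1,0,0,0,1,0,0,0,0,0,0,0,1,0,0,0,1,0
Naja oxiana,0,0,1,1,0,1,1,0,0,0,0,0,0,0,1,1,1,0,0
Walterinnesia morgani,0,0,0,0,1,0,0,0,0,0,0,0,1,1,0,0,0,0,1
Gloydius caucasicus (clade i),0,0,1,1,0,0,0,0,1,0,0,0,0,0,0,1,0,0,0
Gloydius caucasicus (clade ii),0,0,1,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
Gloydius caucasicus (clade iii),0,0,1,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
Gloydius caucasicus (clade iv),0,0,1,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0
Cerastes gasperettii,0,0,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Echis carinatus sochureki,0,1,0,0,1,1,1,0,0,0,0,1,0,1,0,1,1,1,1
Eristicophis macmahoni,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1,0,0
Macrovipera lebetina chernovi,0,0,1,1,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0
Macrovipera lebetina obtusa,0,0,1,0,0,1,1,0,1,1,1,1,1,0,0,0,0,0,0
Macrovipera razii,0,0,1,0,1,1,1,0,0,0,0,1,1,1,0,0,0,0,0
Montivipera kuhrangica,0,0,1,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0
Montivipera latifii,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
Montivipera raddei,0,0,1,0,0,0,0,0,0,1,1,1,0,0,0,0,0,0,0
Montivipera raddei albicornuta,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
Montivipera wagneri,0,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
Pseudocerastes persicus,0,0,1,0,1,1,1,0,0,0,0,1,1,1,0,1,1,1,0
Pseudocerastes urarachnoides,0,0,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0
Vipera eriwanensis,0,0,1,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0
Vipera eriwanensis ebneri,0,0,1,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0
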