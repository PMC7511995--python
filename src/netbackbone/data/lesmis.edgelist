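# node_u node_v weight
Babet Brujon 3
Babet Claquesous 4
Babet Montparnasse 2
Bahorel Bossuet 4
Bahorel Grantaire 1
Bahorel Joly 5
Bahorel MmeHucheloup 1
Bamatabois Brevet 1
Bamatabois Champmathieu 2
Bamatabois Chenildieu 1
Bamatabois Cochepaille 1
Bamatabois Judge 2
Blacheville Dahlia 3
Blacheville Fantine 3
Blacheville Favourite 4
Blacheville Zephine 3
Bossuet Grantaire 3
Bossuet Joly 7
Bossuet MmeHucheloup 1
Brevet Chenildieu 2
Brevet Cochepaille 2
Champmathieu Brevet 2
Champmathieu Chenildieu 2
Champmathieu Cochepaille 2
Chenildieu Cochepaille 2
Child1 Child2 3
Claquesous Brujon 1
Claquesous Montparnasse 2
Combeferre Bahorel 5
Combeferre Bossuet 9
Combeferre Courfeyrac 13
Combeferre Feuilly 5
Combeferre Grantaire 1
Combeferre Joly 5
Combeferre Prouvaire 2
Cosette Gillenormand 3
Cosette Javert 1
Cosette LtGillenormand 1
Cosette Marius 21
Cosette MlleGillenormand 2
Cosette Toussaint 2
Cosette Woman2 1
Courfeyrac Bahorel 6
Courfeyrac Bossuet 12
Courfeyrac Grantaire 2
Courfeyrac Joly 5
Courfeyrac MmeHucheloup 1
Dahlia Fantine 4
Dahlia Zephine 4
Enjolras Bahorel 4
Enjolras Bossuet 10
Enjolras Claquesous 1
Enjolras Combeferre 15
Enjolras Courfeyrac 17
Enjolras Feuilly 6
Enjolras Grantaire 3
Enjolras Joly 5
Enjolras MmeHucheloup 1
Enjolras Prouvaire 4
Eponine Anzelma 2
Eponine Babet 1
Eponine Brujon 1
Eponine Claquesous 1
Eponine Courfeyrac 1
Eponine Gueulemer 1
Eponine Mabeuf 1
Eponine Marius 5
Eponine Montparnasse 1
Fameuil Blacheville 4
Fameuil Dahlia 3
Fameuil Fantine 3
Fameuil Favourite 3
Fameuil Zephine 3
Fantine Bamatabois 1
Fantine Javert 5
Fantine MmeThenardier 2
Fantine Perpetue 1
Fantine Simplice 2
Fantine Thenardier 1
Fauchelevent Gribier 2
Fauchelevent MotherInnocent 3
Favourite Dahlia 5
Favourite Fantine 4
Favourite Zephine 4
Feuilly Bahorel 3
Feuilly Bossuet 6
Feuilly Courfeyrac 6
Feuilly Grantaire 1
Feuilly Joly 5
Gavroche Babet 1
Gavroche Bahorel 5
Gavroche Bossuet 5
Gavroche Brujon 1
Gavroche Child1 2
Gavroche Child2 2
Gavroche Combeferre 6
Gavroche Courfeyrac 7
Gavroche Enjolras 7
Gavroche Feuilly 2
Gavroche Grantaire 1
Gavroche Gueulemer 1
Gavroche Joly 3
Gavroche Mabeuf 1
Gavroche Marius 4
Gavroche MmeHucheloup 1
Gavroche Montparnasse 1
Gavroche Prouvaire 1
Gillenormand BaronessT 1
Gillenormand LtGillenormand 1
Gillenormand Magnon 1
Gillenormand Marius 12
Gillenormand MlleGillenormand 9
Grantaire MmeHucheloup 1
Gueulemer Babet 6
Gueulemer Brujon 3
Gueulemer Claquesous 4
Gueulemer Montparnasse 2
Javert Babet 2
Javert Bamatabois 1
Javert Claquesous 1
Javert Enjolras 6
Javert Fauchelevent 1
Javert Gavroche 1
Javert Gueulemer 1
Javert Montparnasse 1
Javert Simplice 1
Javert Toussaint 1
Javert Woman1 1
Javert Woman2 1
Joly Grantaire 2
Joly MmeHucheloup 1
Judge Brevet 2
Judge Champmathieu 3
Judge Chenildieu 2
Judge Cochepaille 2
Listolier Blacheville 4
Listolier Dahlia 3
Listolier Fameuil 4
Listolier Fantine 3
Listolier Favourite 3
Listolier Tholomyes 4
Listolier Zephine 3
LtGillenormand Marius 1
Mabeuf Bahorel 2
Mabeuf Bossuet 1
Mabeuf Combeferre 2
Mabeuf Courfeyrac 2
Mabeuf Enjolras 1
Mabeuf Feuilly 1
Mabeuf Joly 1
Mabeuf MotherPlutarch 3
Marguerite Fantine 2
Marius Bahorel 1
Marius BaronessT 1
Marius Bossuet 5
Marius Combeferre 5
Marius Courfeyrac 9
Marius Enjolras 7
Marius Feuilly 1
Marius Joly 2
Marius Mabeuf 1
MlleBaptistine MmeMagloire 6
MlleBaptistine Valjean 3
MlleGillenormand LtGillenormand 2
MlleGillenormand Marius 6
MlleGillenormand MlleVaubois 1
MlleGillenormand MmePontmercy 1
MmeBurgon Gavroche 2
MmeBurgon Jondrette 1
MmeMagloire Valjean 3
MmeThenardier Anzelma 1
MmeThenardier Babet 1
MmeThenardier Claquesous 1
MmeThenardier Cosette 4
MmeThenardier Eponine 2
MmeThenardier Gueulemer 1
MmeThenardier Javert 1
MmeThenardier Magnon 1
MmeThenardier Thenardier 13
Montparnasse Brujon 1
Myriel Champtercier 1
Myriel Count 2
Myriel CountessDeLo 1
Myriel Cravatte 1
Myriel Geborand 1
Myriel MlleBaptistine 8
Myriel MmeMagloire 10
Myriel OldMan 1
Myriel Valjean 5
Napoleon Myriel 1
Perpetue Simplice 2
Pontmercy Marius 1
Pontmercy MmePontmercy 1
Prouvaire Bahorel 2
Prouvaire Bossuet 2
Prouvaire Courfeyrac 3
Prouvaire Feuilly 2
Prouvaire Grantaire 1
Prouvaire Joly 2
Thenardier Anzelma 2
Thenardier Babet 6
Thenardier Boulatruelle 1
Thenardier Brujon 3
Thenardier Claquesous 4
Thenardier Cosette 1
Thenardier Eponine 3
Thenardier Gavroche 1
Thenardier Gueulemer 5
Thenardier Javert 5
Thenardier Marius 2
Thenardier Montparnasse 1
Thenardier Pontmercy 1
Tholomyes Blacheville 4
Tholomyes Cosette 1
Tholomyes Dahlia 3
Tholomyes Fameuil 4
Tholomyes Fantine 3
Tholomyes Favourite 3
Tholomyes Marius 1
Tholomyes Zephine 3
Valjean Babet 1
Valjean Bamatabois 2
Valjean Bossuet 1
Valjean Brevet 2
Valjean Champmathieu 3
Valjean Chenildieu 2
Valjean Claquesous 1
Valjean Cochepaille 2
Valjean Cosette 31
Valjean Enjolras 4
Valjean Fantine 9
Valjean Fauchelevent 8
Valjean Gavroche 1
Valjean Gervais 1
Valjean Gillenormand 2
Valjean Gueulemer 1
Valjean Isabeau 1
Valjean Javert 17
Valjean Judge 3
Valjean Labarre 1
Valjean Marguerite 1
Valjean Marius 19
Valjean MlleGillenormand 2
Valjean MmeDeR 1
Valjean MmeThenardier 7
Valjean Montparnasse 1
Valjean MotherInnocent 1
Valjean Scaufflaire 1
Valjean Simplice 3
Valjean Thenardier 12
Valjean Toussaint 1
Valjean Woman1 2
Valjean Woman2 3
Zephine Fantine 4
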