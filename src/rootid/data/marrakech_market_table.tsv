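sample_id	vernacular_name	putative_name	id_confirmed	final_id
EM449	'Aqirqarha [good]	Anacyclus pyrethrum	Genus confirmed	Anacyclus sp.
EM408	'Aqirqarha [highest]	Anacyclus pyrethrum	Genus confirmed	Anacyclus sp.
EM444	'Aqirqarha [highest]	Anacyclus pyrethrum	Genus confirmed	Anacyclus sp.
EM448	'Aqirqarha [worst]	Anacyclus pyrethrum	Genus confirmed	Anacyclus sp.
EM362	'Aqirqarha [secondary]	Anacyclus pyrethrum	Different genus	Catananche sp.
EM361	'Aqirqarha [highest]	Anacyclus pyrethrum	Different genus	Catananche caespitosa
EM416	'Aqirqarha [secondary]	Anacyclus pyrethrum	Different genus	Catananche sp.
EM450	'Aqirqarha [secondary]	Anacyclus pyrethrum	Genus confirmed	Anacyclus sp.
EM399	'Arq assus	Glycyrrhiza glabra	Genus confirmed	Glycyrrhiza sp.
EM409	'Arq assus lbldi	Glycyrrhiza glabra	Genus confirmed	Glycyrrhiza sp.
EM378	'Arq assus lhchich	Glycyrrhiza glabra	Genus confirmed	Glycyrrhiza sp.
EM373	'Arq assus lqash	Glycyrrhiza glabra	Genus confirmed	Glycyrrhiza sp.
EM357	'Erq wadmi lbldi	Armeria sp.	Species confirmed	Armeria sp.
EM358	'Erq wadmi rroumi	Armeria sp.	Species confirmed	Armeria sp.
EM429	'Ud-mserser [highest]	Polygonum aviculare; Daucus crinitus	Species confirmed	Daucus crinitus
EM453	'Ud-mserser [highest]	Polygonum aviculare; Daucus crinitus	Species confirmed	Daucus crinitus
EM417	'Ud-mserser [secondary]	Polygonum aviculare; Daucus crinitus	Family confirmed	Thapsia sp.
EM451	'Ud-mserser [secondary]	Polygonum aviculare; Daucus crinitus	Different genus	Thapsia sp.
EM437	Addad	Carlina gummifera	Genus confirmed	Carlina gummifera
EM374	Addad bjlftou	Carlina gummifera	Species confirmed	Carlina gummifera
EM397	Addad dkr	Carlina gummifera	Species confirmed	Carlina gummifera
EM380	Addad lmjllaf	Carlina gummifera	Species confirmed	Carlina gummifera
EM396	Addad ntwa	Carlina gummifera	Family confirmed	Asteraceae
EM431	'Ansal	Drimia maritima	Species confirmed	Drimia sp.
EM446	As-susan	Iris x germanica	Genus confirmed	Iris sp.
EM365	Besbas lbldi	Foeniculum vulgare	Species confirmed	Anethum foeniculoides; Foeniculum vulgare
EM387	Besbas lbldi	Foeniculum vulgare	Species confirmed	Anethum foeniculoides; Foeniculum vulgare
EM369	Besbas lbldi	Foeniculum vulgare	Different family	Echinops sp.
EM366	Besbas lboustani	Foeniculum vulgare	Species confirmed	Anethum foeniculoides; Foeniculum vulgare
EM372	Besbas lboustani	Foeniculum vulgare	Species confirmed	Anethum foeniculoides; Foeniculum vulgare
EM404	Bid al-gul	Mandragora autumnalis	Different species	Mandragora officinarum
EM436	Buglam sahrawi	Spergularia marginata	Family confirmed	Caryophyllaceae
EM377	Bougoudz	Unidentified	Previously unknown	Dioscorea communis
EM452	Bougoudz	Unidentified	Previously unknown	Dioscorea communis
OA1	Bougoudz	Unidentified	Previously unknown	Dioscorea communis
OA2	Bougoudz	Unidentified	Previously unknown	Dioscorea communis
OA4	Bougoudz	Unidentified	Previously unknown	Dioscorea communis
EM447	Bu-zfur	Daucus crinitus	Different genus	Kundmannia sicula
EM405	Brztm	Aristolochia fontanesii	Genus confirmed	Aristolochia sp.
EM410	Bukbuka	Colchicum autumnale	Different family	Bunium sp.
EM434	Dbag lbldi	Quercus sp.	Species confirmed	Quercus ilex
EM414	Deryas	Thapsia garganica	Family confirmed	Apiaceae
EM371	Frifra	Magydaris panacifolia	Different genus	Kundmannia sicula
EM412	Frifra	Magydaris panacifolia	Different genus	Anethum foeniculoides; Foeniculum vulgare
EM438	Fuwwa	Rubia peregrina; Rubia tinctorum	Genus confirmed	Rubia sp.
EM379	Fuwwa lfrouguiyya	Rubia peregrina; Rubia tinctorum	Family confirmed	Rubiaceae
EM390	Fuwwa lfrouguiyya	Rubia peregrina; Rubia tinctorum	Genus confirmed	Rubia sp.
EM391	Fuwwa rqiqa (jbal nawahi mrrakch)	Rubia peregrina; Rubia tinctorum	Different genus	Galium sp.
EM398	Fwila	Erophaca baetica subsp. baetica	Species confirmed	Erophaca baetica subsp. baetica
EM430	Horsef	Cynara cardunculus	Genus confirmed	Cynara sp.
EM395	Horsef rroumi	Cynara cardunculus	Genus confirmed	Echinops spinosissimus
EM402	L-fijel	Ruta montana	Species confirmed	Ruta montana
EM439	L-gseb	Arundo donax	Species confirmed	Arundo donax
EM443	L-gseb	Arundo donax	Species confirmed	Arundo donax
EM442	L-harmel	Peganum harmala	Different family	Carlina brachylepis
OA3	L-harmel	Peganum harmala	Different family	Vitis sp.
EM432	Lghzghaz	Carlina involucrata	Species confirmed	Carlina brachylepis
EM433	Lklkh	Ferula communis	Species confirmed	Ferula communis
EM435	Luwwaya	Smilax aspera	Species confirmed	Smilax aspera
EM382	Mgizla	Eryngium triquetrum	Genus confirmed	Eryngium sp.
EM424	Mgizla	Eryngium triquetrum	Genus confirmed	Eryngium sp.
EM422	Ndkhir	Unidentified	Previously unknown	Dioscorea communis
EM388	Nnjem lbori	Cynodon dactylon	Family confirmed	Poaceae
EM389	Nnjem lmawi	Cynodon dactylon	Different genus	Panicum sp.
EM427	Oudn lhllouf	Pulicaria arabica	Different species	Pulicaria odora
EM403	Sargina	Corrigiola telephiifolia	Species confirmed	Corrigiola litoralis subsp. litoralis
EM368	Sargina l3adia	Corrigiola telephiifolia	Different genus	Silene mentagensis
EM376	Sargina l3adia	Corrigiola telephiifolia	Species confirmed	Corrigiola litoralis subsp. telephiifolia
EM367	Sargina lmsouwsa	Corrigiola telephiifolia	Species confirmed	Corrigiola litoralis subsp. telephiifolia
EM421	Sargina lmsouwsa	Corrigiola telephiifolia	Species confirmed	Corrigiola litoralis subsp. telephiifolia
EM423	Sargina rrahmania	Corrigiola telephiifolia	Family confirmed	Caryophyllaceae
EM440	Ssder	Ziziphus lotus	Species confirmed	Ziziphus lotus
EM413	Tafga	Rhaponticum acaule	Genus confirmed	Rhaponticum sp.
OA10	Tafga	Rhaponticum acaule	Family confirmed	Asteraceae
EM411	Talh	Acacia sp.	Species confirmed	Acacia gummifera
EM363	Talh dkr	Acacia sp.	Species confirmed	Acacia gummifera
EM364	Talh ntwa	Acacia sp.	Species confirmed	Acacia gummifera
EM407	Taskra	Echinops spinosissimus	Genus confirmed	Echinops sp.
EM356	Terta	Withania frutescens	Different family	Kundmannia sicula
OA11	Terta	Withania frutescens	Genus confirmed	Withania sp.
OA8	Terta	Withania frutescens	Genus confirmed	Withania sp.
EM428	Tigigest	Silene sp.	Species confirmed	Silene vulgaris
EM425	Zziyata	Kundmannia sicula; Limoniastrum guyonianum; Limoniastrum ifniense; Conium maculatum; Apium nodiflorum; Polygonum maritimum	Species confirmed	Kundmannia sicula
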