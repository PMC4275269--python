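event_id,group_id,latitude,longitude,year,month,depth_min_m,depth_max_m,species,higher_group,metric,intensity,co_threats,sources
ev01,ev01,44.0,9.15,1983,9,0,25,Corallium rubrum;Spongia officinalis,cnidarians;sponges,% affected colonies,high,n.r.,pub01
ev02,ev02,44.0,9.15,1986,9,0,20,Spongia lamella;Hippospongia communis,sponges;sponges,% affected colonies,medium,n.r.,pub02
ev03,ev03,42.05,3.22,1992,n.r.,0,30,Ircinia variabilis;Ircinia oros;Sarcotragus spinosulus,sponges;sponges;sponges,% affected colonies,high,disease outbreak,pub03;pub04
ev04,ev04,43.0,6.3,1993,10,5,25,Paramuricea clavata;Eunicella cavolinii,cnidarians;cnidarians,% affected colonies,low,n.r.,pub05
ev05,ev05,40.25,17.9,1994,8,n.r.,n.r.,Spongia officinalis;Sarcotragus fasciculatus;Petrosia ficiformis,sponges;sponges;sponges,% affected colonies,high,n.r.,pub06
ev06,ev06,44.0,9.15,1999,9,0,70,Paramuricea clavata;Eunicella singularis;Eunicella cavolinii;Eunicella verrucosa;Corallium rubrum;Cladocora caespitosa;Spongia officinalis;Spongia lamella;Hippospongia communis;Ircinia variabilis;Ircinia oros;Pentapora fascialis;Myriapora truncata;Pinna nobilis;Arca noae;Halocynthia papillosa;Microcosmus sabatieri,cnidarians;cnidarians;cnidarians;cnidarians;cnidarians;cnidarians;sponges;sponges;sponges;sponges;sponges;bryozoans;bryozoans;bivalves;bivalves;ascidians;ascidians,% affected colonies,high,prolonged stratification,pub07;pub08;pub09
ev06,ev06,43.0,6.3,1999,9,0,26,Paramuricea clavata;Eunicella singularis;Eunicella cavolinii;Eunicella verrucosa;Corallium rubrum;Sarcotragus spinosulus;Sarcotragus fasciculatus;Petrosia ficiformis;Cacospongia scalaris;Adeonella calveti;Spondylus gaederopus,cnidarians;cnidarians;cnidarians;cnidarians;cnidarians;sponges;sponges;sponges;sponges;bryozoans;bivalves,% affected colonies,high,prolonged stratification,pub10;pub11
ev06,ev06,39.5,2.5,1999,9,30,50,Eunicella singularis,cnidarians,% affected colonies,67,n.r.,pub12
ev07,ev07,40.2,24.0,1999,9,0,40,Paramuricea clavata;Oculina patagonica;Aplysina aerophoba,cnidarians;cnidarians;sponges,% affected colonies,medium,n.r.,pub13
ev08,ev08,41.5,10.0,2001,9,0,35,Paramuricea clavata;Parazoanthus axinellae,cnidarians;cnidarians,% affected colonies,low,n.r.,pub14
ev09,ev09,40.6,14.2,2002,9,0,30,Astroides calycularis;Balanophyllia europaea,cnidarians;cnidarians,% affected colonies,medium,n.r.,pub15
ev10,ev10,44.0,9.15,2003,9,0,40,Astroides calycularis;Balanophyllia europaea;Leptopsammia pruvoti;Madracis pharensis;Cacospongia mollior;Aplysina aerophoba;Aplysina cavernicola;Smittina cervicornis,cnidarians;cnidarians;cnidarians;cnidarians;sponges;sponges;sponges;bryozoans,% affected colonies,high,heatwave,pub16;pub17
ev10,ev10,43.0,6.3,2003,8,0,30,Alcyonium acaule;Alcyonium coralloides;Paralcyonium spinulosum;Axinella polypoides;Axinella damicornis;Agelas oroides;Lima lima,cnidarians;cnidarians;cnidarians;sponges;sponges;sponges;bivalves,% affected colonies,high,heatwave,pub18;pub19
ev10,ev10,40.6,14.2,2003,9,0,32,Cladocora caespitosa;Cereus pedunculatus;Chondrosia reniformis,cnidarians;cnidarians;sponges,% affected colonies,medium,heatwave,pub20
ev10,ev10,41.5,10.0,2003,9,0,30,Paramuricea clavata;Crambe crambe;Schizomavella mamillata;Mytilus galloprovincialis,cnidarians;sponges;bryozoans;bivalves,% affected colonies,high,heatwave,pub21
ev10,ev10,39.5,2.5,2003,8,0,40,Aglaophenia octodonta;Dysidea avara;Reteporella grimaldii,cnidarians;sponges;bryozoans,% affected colonies,medium,heatwave,pub22;pub23
ev11,ev11,40.6,14.2,2005,9,10,40,Leptopsammia pruvoti;Pyura dura,cnidarians;ascidians,% affected colonies,low,n.r.,pub24
ev12,ev12,39.5,2.5,2005,9,0,30,Eunicella singularis;Ophidiaster ophidianus,cnidarians;other,% affected colonies,low,n.r.,pub25
ev13,ev13,44.0,9.15,2006,10,0,30,Eunicella cavolinii;Haliclona mediterranea;Aplidium conicum,cnidarians;sponges;ascidians,% affected colonies,medium,n.r.,pub26
ev14,ev14,43.0,6.3,2006,7,0,20,Eudendrium racemosum;Paracentrotus lividus,cnidarians;other,% affected colonies,low,n.r.,pub27
ev15,ev15,39.5,2.5,2007,9,0,30,Eunicella singularis;Hacelia attenuata,cnidarians;other,% affected colonies,low,n.r.,pub28
ev16,ev16,44.0,9.15,2008,10,0,30,Paramuricea clavata;Clathrina clathrus,cnidarians;sponges,% affected colonies,medium,n.r.,pub29
ev17,ev17,41.5,10.0,2008,9,0,35,Paramuricea clavata,cnidarians,% affected colonies,high,n.r.,pub30
ev18,ev18,39.5,2.5,2008,10,0,30,Eunicella singularis;Eunicella verrucosa,cnidarians;cnidarians,% affected colonies,medium,n.r.,pub31
ev19,ev19,44.0,9.15,2009,10,0,30,Paramuricea clavata;Eunicella cavolinii,cnidarians;cnidarians,% affected colonies,medium,n.r.,pub32
ev19,ev19,40.6,14.2,2009,9,0,30,Cladocora caespitosa;Frondipora verrucosa,cnidarians;bryozoans,% affected colonies,low,n.r.,pub33
ev19,ev19,40.05,18.45,2009,8,0,20,Spongia officinalis;Ircinia variabilis;Turbicellepora avicularis,sponges;sponges;bryozoans,% affected colonies,high,n.r.,pub34
ev19,ev19,43.55,13.6,2009,9,0,15,Pinna nobilis;Halocynthia papillosa;Sphaerechinus granularis,bivalves;ascidians;other,% affected colonies,medium,n.r.,pub35
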