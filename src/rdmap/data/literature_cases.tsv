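case_id	target_xref	target_name	hpo_terms	reported_rank	reported_score
case01	OMIM:603147	Congenital disorder of glycosylation	HP:0025356,HP:0001252,HP:0001644,HP:0001250,HP:0000486,HP:0006610	6	0.0625
case02	OMIM:255200	Centronuclear myopathies	HP:0009073,HP:0000297,HP:0000508,HP:0000602,HP:0001315,HP:0001256	4	0.0486
case03	OMIM:277000	Mayer-Rokitansky-Kuster-Hauser syndrome	HP:0002089,HP:0000122,HP:0000151,HP:0008726	4	0.0937
case04	OMIM:241530	Hereditary hypophosphatemic rickets with hypercalciuria	HP:0002148,HP:0002150	1	0
case05	OMIM:203800	Alstrom syndrome	HP:0000662,HP:0000618,HP:0012330,HP:0000822,HP:0000819,HP:0000510,HP:0000518	1	0.0535
case06	OMIM:119600	Cleidocranial dysplasia	HP:0000684,HP:0000164,HP:0000316,HP:0011069	1	0
case07	OMIM:200100	Abetalipoproteinemia	HP:0002630,HP:0001251,HP:0001324,HP:0001315	4	0.0416
case08	OMIM:604290	Aceruloplasminemia	HP:0001935,HP:0001260,HP:0001288,HP:0000819,HP:0001903,HP:0001300	1	0.0416
case09	OMIM:606690	Lymphangioleiomyomatosis	HP:0100749,HP:0002094,HP:0002107	1	0
case10	OMIM:226980	Wolcott-Rallison syndrome	HP:0006554,HP:0001298,HP:0000083,HP:0002654	1	0.0208
case11	OMIM:253200	Mucopolysaccharidosis type 6	HP:0000280,HP:0000470,HP:0000158,HP:0002808,HP:0012471	1	0.0083
case12	OMIM:175700	Greig cephalopolysyndactyly syndrome	HP:0000256,HP:0011304,HP:0001159,HP:0001162,HP:0005873	1	0.016
case13	OMIM:301500	Fabry disease	HP:0001014	1	0
case14	OMIM:609192	Loeys-Dietz syndrome	HP:0100490,HP:0001193,HP:0001776,HP:0000592,HP:0000308,HP:0000218,HP:0000193	1	0.0628
case15	OMIM:146300	Hypophosphatasia	HP:0002757,HP:0001363,HP:0006480	1	0.0138
case16	OMIM:308700	Kallmann syndrome	HP:0000876,HP:0003187,HP:0000458,HP:0000365,HP:0009804	1	0.0249
case17	OMIM:214500	Chediak-Higashi syndrome	HP:0007340,HP:0000726,HP:0001251,HP:0007338,HP:0002067,HP:0000704	4	0.0972
case18	OMIM:235730	Mowat-Wilson syndrome	HP:0000194,HP:0000534,HP:0002007,HP:0000490,HP:0000431,HP:0000486	1	0
case19	OMIM:251260	Nijmegen breakage syndrome	HP:0000252,HP:0000340,HP:0000278,HP:0000400,HP:0000414	1	0.0116
case20	OMIM:222300	Wolfram syndrome	HP:0000819,HP:0000648,HP:0000873,HP:0000365,HP:0002020	1	0.0333
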