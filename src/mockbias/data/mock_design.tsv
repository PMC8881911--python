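taxon	order	pool_1	pool_2	pool_3	pool_4	pool_5	pool_6	pool_7	pool_8
Carpophilus davidsoni	Coleoptera	25	50	5	10	25	50	5	10
Carpophilus truncatus	Coleoptera	1	1	1	1	1	1	1	1
Bactrocera tryoni	Diptera	1	1	1	1	1	1	1	1
Bradysia nr. ocellaris	Diptera	0	0	0	0	1	0	1	0
Drosophila hydei	Diptera	1	1	1	1	1	1	1	1
Drosophila melanogaster	Diptera	5	10	25	50	5	10	25	50
Drosophila simulans	Diptera	1	1	1	1	1	1	1	1
Scaptodrosophila lativittata	Diptera	1	1	1	1	1	1	1	1
Acizzia alternata	Hemiptera	1	1	1	1	1	1	1	1
Acizzia solanicola	Hemiptera	10	25	50	5	10	25	50	5
Acizzia sp.	Hemiptera	1	1	1	1	1	1	1	1
Diuraphis noxia	Hemiptera	1	1	1	1	1	1	1	1
Metopolophium dirhodum	Hemiptera	1	1	1	1	1	1	1	1
Rhopalosiphum padi	Hemiptera	1	1	1	1	1	1	1	1
Aphidius colemani	Hymenoptera	36	5	6	12	36	4	9	20
Lysiphlebus testaceipes	Hymenoptera	14	0	4	13	14	1	1	5
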