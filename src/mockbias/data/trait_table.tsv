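taxon	primer	fwd_mismatch	rev_mismatch	gc	volume_mm3	hardness
Carpophilus davidsoni	fwhF2-fwhR2n	0.12	0.09	0.37	3.80	3
Carpophilus truncatus	fwhF2-fwhR2n	0.04	0.04	0.35	3.91	3
Bactrocera tryoni	fwhF2-fwhR2n	0	0.04	0.37	26.51	2
Bradysia nr. ocellaris	fwhF2-fwhR2n	0.08	0	0.34	0.25	2
Drosophila hydei	fwhF2-fwhR2n	0.04	0	0.33	2.19	2
Drosophila melanogaster	fwhF2-fwhR2n	0	0	0.30	1.14	2
Drosophila simulans	fwhF2-fwhR2n	0	0	0.32	0.79	2
Scaptodrosophila lativittata	fwhF2-fwhR2n	0	0	0.28	3.09	2
Acizzia alternata	fwhF2-fwhR2n	0	0.04	0.30	0.22	1
Acizzia solanicola	fwhF2-fwhR2n	0	0.04	0.32	0.47	1
Acizzia sp.	fwhF2-fwhR2n	0.08	0.09	0.32	1.18	1
Diuraphis noxia	fwhF2-fwhR2n	0.04	0	0.20	0.50	1
Metopolophium dirhodum	fwhF2-fwhR2n	0.04	0	0.22	0.65	1
Rhopalosiphum padi	fwhF2-fwhR2n	0.04	0	0.19	0.18	1
Aphidius colemani	fwhF2-fwhR2n	0	0	0.25	0.32	2
Lysiphlebus testaceipes	fwhF2-fwhR2n	0	0	0.24	0.17	2
Carpophilus davidsoni	fwhF2-HexCOIR4	0.12	0.06	0.38	3.80	3
Carpophilus truncatus	fwhF2-HexCOIR4	0.04	0	0.35	3.91	3
Bactrocera tryoni	fwhF2-HexCOIR4	0	0	0.37	26.51	2
Bradysia nr. ocellaris	fwhF2-HexCOIR4	0.08	0	0.34	0.25	2
Drosophila hydei	fwhF2-HexCOIR4	0.04	0.06	0.33	2.19	2
Drosophila melanogaster	fwhF2-HexCOIR4	0	0	0.30	1.14	2
Drosophila simulans	fwhF2-HexCOIR4	0	0	0.32	0.79	2
Scaptodrosophila lativittata	fwhF2-HexCOIR4	0	0	0.28	3.09	2
Acizzia alternata	fwhF2-HexCOIR4	0	0	0.31	0.22	1
Acizzia solanicola	fwhF2-HexCOIR4	0	0	0.33	0.47	1
Acizzia sp.	fwhF2-HexCOIR4	0.08	0	0.33	1.18	1
Diuraphis noxia	fwhF2-HexCOIR4	0.04	0	0.20	0.50	1
Metopolophium dirhodum	fwhF2-HexCOIR4	0.04	0	0.22	0.65	1
Rhopalosiphum padi	fwhF2-HexCOIR4	0.04	0	0.20	0.18	1
Aphidius colemani	fwhF2-HexCOIR4	0	0	0.25	0.32	2
Lysiphlebus testaceipes	fwhF2-HexCOIR4	0	0	0.25	0.17	2
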