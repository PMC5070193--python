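species	Cdc48	NSF	Pex1	Pex6	Spaf	Spaflike	NVL	Yta7
Blastocystis_hominis	1	1	0	0	1	0	1	0
Plasmodium_Babesia_Theileria	1	1	0	0	1	0	1	0
Oomycetes	1	1	1	1	1	1	1	1
Trichomonas_vaginalis	1	1	0	0	1	0	1	1
Leishmania_Trypanosoma	1	1	1	1	1	0	1	1
Giardia	1	1	0	0	0	0	1	0
Microsporidia	1	1	0	0	0	0	1	0
Entamoeba	1	1	0	0	1	0	1	1
Oikopleura_dioica	1	1	0	0	1	0	1	1
Trichuris_Trichinella	1	1	0	0	1	0	1	0
Parasitic_Platyhelminthes	1	1	0	0	0	0	1	1
Homo_sapiens	1	1	1	1	1	1	1	2
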