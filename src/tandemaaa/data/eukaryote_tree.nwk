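(((((Homo_sapiens:1.0,Oikopleura_dioica:1.0):0.3,(Trichuris_Trichinella:1.0,Parasitic_Platyhelminthes:1.0):0.3):0.3,Microsporidia:1.6):0.3,Entamoeba:1.9):0.5,(((Oomycetes:1.0,Blastocystis_hominis:1.0):0.4,Plasmodium_Babesia_Theileria:1.4):0.5,(Leishmania_Trypanosoma:1.7,(Giardia:1.2,Trichomonas_vaginalis:1.2):0.5):0.2):0.5);
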