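((Naegleria_gruberi,(Naegleria_fowleri,Naegleria_lovaniensis))Heterolobosea,(((Euglena_gracilis,Euglena_longa)Euglena,Rhabdomonas_costata)Euglenida,((Hemistasia_phaeocysticola,(Diplonema_ambulator,(Diplonema_papillatum,Diplonema_japonicum))Diplonema)Diplonemea,(Perkinsela_sp,(Trypanoplasma_borreli,(Bodo_saltans,(Paratrypanosoma_confusum,(((Trypanosoma_brucei,Trypanosoma_vivax)African_trypanosomes,Trypanosoma_cruzi)Trypanosoma,(Blechomonas_ayalai,(Phytomonas_sp,((Angomonas_deanei,Strigomonas_culicis)Strigomonadinae,(((Leishmania_major,Leishmania_tarentolae)Leishmania,Endotrypanum_monterogeii)Leishmania_Endotrypanum,((Crithidia_fasciculata,Leptomonas_seymouri)Crithidia_Lseymouri,Leptomonas_pyrrhocoris)Crithidia_Leptomonas)Leishmaniinae)))Trypanosomatidae_core)Trypanosomatida_crown)Trypanosomatida)Bodonida_Trypanosomatida)Metakinetoplastina)Kinetoplastea)Kinetoplastea_Diplonemea)Euglenozoa)Discoba;
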