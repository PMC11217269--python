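name,centre,window_lo,window_hi,biomolecule_class,assignment,reference
lipid_unsaturated,3011,2996,3026,storage,nu(=C-H) stretch of unsaturated fatty acids,standard lipid CH-stretch assignment
lipid_ch2_asym,2921,2906,2936,storage,nu_as(C-H) of methylene (-CH2) from saturated fatty acids,standard lipid CH-stretch assignment
lipid_ch2_sym,2852,2837,2867,storage,nu_s(C-H) of methylene (-CH2) from saturated lipids,standard lipid CH-stretch assignment
lipid_ester_carbonyl,1744,1719,1769,storage,nu(C=O) ester carbonyl of triglycerides and fatty acids,standard ester carbonyl assignment
protein_amide_ii,1549,1524,1574,functional,amide II; mainly delta(N-H) of amides,standard protein amide assignment
carboxylate,1400,1375,1425,functional,nu_s(COO-) of carboxylated molecules,standard carboxylate assignment
phosphodiester,1241,1216,1266,functional,nu_as(PO2-) of phosphodiester backbones,standard nucleic-acid/phospholipid assignment
carbohydrate,1168,1146,1191,storage,nu_s(C-O) of carbohydrates,standard carbohydrate assignment
silica,1080,1055,1105,functional,nu_s(Si-O) of biogenic silica,standard silica assignment
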