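# Context metadata for the Pineland assemblage fixture. Period labels follow the
# site chronology; strat_order orders the Operation P column bottom-up (105 earliest).
context_id,site_area,period_label,strat_order
Old Mound 1 (A-8-101),old_mound,Caloosahatchee I,
Surf Clam Ridge (Trench 11B-93),surf_clam_ridge,Caloosahatchee I,
Low Mound (A-1-77-1),low_mound,Caloosahatchee I,
Old Mound 2 (A-16-92),old_mound,Caloosahatchee IIA,
Brown's Complex 1 (C-6-92-1),browns_complex,Caloosahatchee IIA,
Brown's Complex 2 (C-5-88-2),browns_complex,Caloosahatchee IIA,
Brown's Complex 3 (C-5-79-1),browns_complex,Caloosahatchee IIA,
Randell Complex 1 (A-Prof-63),randell_complex,Caloosahatchee IIB,
Randell Complex 2 (A-Prof-55),randell_complex,Caloosahatchee IIB,
Brown's Complex Mound 2a (I-2-73),browns_mound_2,Caloosahatchee III,
Brown's Complex Mound 2b (I-2-66),browns_mound_2,Caloosahatchee IV,
Operation P (P-10-99),operation_p,Operation P level 99,4
Operation P (P-10-101),operation_p,Operation P level 101,3
Operation P (P-10-103),operation_p,Operation P level 103,2
Operation P (P-10-105),operation_p,Operation P level 105,1
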