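# Per-species key-residue variants relative to the human reference of each
# clade (hT2R10 for mode R10, hT2R46 for mode R46), from the published
# per-species variant annotations.  An empty variation list means all key
# positions are identical to the human receptor.
# species	mode	variations (bw:residue, comma-separated)
Ptr_T2R10	R10	
Ggo_T2R10	R10	
Nle_T2R10	R10	
Mmu_T2R10	R10	
Ppy_T2R10	R10	
Pha_T2R10	R10	
Clu_T2R10	R10	
Lpi_T2R10	R10	
Vfe_T2R10	R10	
Vco_T2R10	R10	
Vvu_T2R10	R10	
Cbr_T2R10	R10	
Vze_T2R10	R10	
Ame_T2R10	R10	
Ssc_T2R10	R10	3.37:H,5.39:S
Bta_T2R10	R10	3.33:I,5.43:F
Oar_T2R10	R10	3.33:I,5.40:H,7.39:I,7.42:R
Cja_T2R10	R10	3.33:I,7.39:I,7.42:S
Ggo_T2R46	R46	3.36:S
Ppa_T2R46	R46	6.63:K
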