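region,caspian_hyrcanian_mixed_forests,elburz_range_forest_steppe,eastern_anatolian_montane_steppe,azerbaijan_shrub_desert_and_steppe,zagros_mountains_forest_steppe,middle_east_steppe,mesopotamian_shrub_desert,tigris_euphrates_alluvial_salt_marsh,south_iran_nubo_sindian_desert_and_semi_desert,persian_gulf_desert_and_semi_desert,indus_river_delta_arabian_sea_mangroves,central_persian_desert_basins,kuh_rud_and_eastern_iran_montane_woodlands,registan_north_pakistan_sandy_desert,baluchistan_xeric_woodlands,kopet_dag_woodlands_and_forest_steppe
Ce,0,0,0,0,0,0,0,0,0,0,0,1,1,0,0,0
Ca,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
A,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
M,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
R,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0
Z,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0
WZ,0,0,0,0,1,1,1,0,0,0,0,0,0,0,0,0
Kh,0,0,0,0,0,1,1,1,1,0,0,0,0,0,0,0
T,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
K,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
S,0,0,0,0,0,0,0,0,0,0,0,1,0,1,1,0
B,0,0,0,0,0,0,0,0,1,0,0,0,1,0,1,0
I,0,0,0,0,0,0,0,0,1,1,1,0,0,0,0,0
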