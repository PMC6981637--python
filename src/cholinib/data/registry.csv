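id,series,r1_c6,r5_c8,aryl,formula,n_stereocenters,yield_pct,state,esi_mh,printed_mass
5a,5,H,H,phenyl,C23H25N3O2,2,74,Yellow oil,376,
5b,5,H,H,4-OMe,C24H27N3O3,2,64,Yellow oil,406,
5c,5,H,H,"3,4-diOMe",C25H29N3O4,2,65,Yellow oil,436,
5d,5,H,H,"3,4,5-triOMe",C26H31N3O5,2,65,Red oil,466,
5e,5,CH3,H,phenyl,C24H27N3O2,2,65,Orange oil,390,
5f,5,CH3,H,4-OMe,C25H29N3O3,2,70,Orange oil,420,
5g,5,CH3,H,"3,4-diOMe",C26H31N3O4,2,63,Orange oil,450,
5h,5,CH3,H,"3,4,5-triOMe",C27H33N3O5,2,68,Orange oil,480,
5i,5,OCH3,H,phenyl,C24H27N3O3,2,77,Red oil,406,
5j,5,OCH3,H,4-OMe,C25H29N3O4,2,70,Red oil,436,
5k,5,OCH3,H,"3,4-diOMe",C26H31N3O5,2,76,Red oil,466,
5l,5,OCH3,H,"3,4,5-triOMe",C27H33N3O6,2,68,Red oil,496,
5m,5,Cl,H,phenyl,C23H24ClN3O2,2,74,Yellow oil,410,
5n,5,Cl,H,4-OMe,C24H26ClN3O3,2,64,Yellow oil,440,
5o,5,Cl,H,"3,4-diOMe",C25H28ClN3O4,2,75,Yellow oil,470,
5p,5,Cl,H,"3,4,5-triOMe",C26H30ClN3O5,2,75,Yellow oil,500,
6a,6,H,H,phenyl,C23H23N3O2,1,55,Orange oil,374.1,
6b,6,H,H,4-OMe,C24H25N3O3,1,65,Red oil,,
6c,6,H,H,"3,4,5-triOMe",C26H29N3O5,1,75,Brown oil,,
6d,6,CH3,H,phenyl,C24H25N3O2,1,72,Red oil,,
6e,6,CH3,H,4-OMe,C25H27N3O3,1,64,Red oil,,
6f,6,CH3,Cl,"3,4-diOMe",C26H28ClN3O4,1,58,Beige solid,482.0,
6g,6,CH3,H,"3,4,5-triOMe",C27H31N3O5,1,63,Red oil,478.3,
6h,6,OCH3,H,phenyl,C24H25N3O3,1,42,Brown oil,,403.48
6i,6,OCH3,H,4-OMe,C25H27N3O4,1,74,Red oil,,
6j,6,OCH3,Cl,"3,4-diOMe",C26H28ClN3O5,1,86,Beige solid,,
6k,6,OCH3,H,"3,4,5-triOMe",C27H31N3O6,1,74,Red oil,,
6l,6,Cl,H,phenyl,C23H22ClN3O2,1,55,Red oil,,
6m,6,Cl,H,4-OMe,C24H24ClN3O3,1,51,Orange oil,,
6n,6,Cl,H,"3,4-diOMe",C25H26ClN3O4,1,68,Orange oil,,
6o,6,Cl,Cl,"3,4-diOMe",C25H25Cl2N3O4,1,88,Orange solid,,
6p,6,Cl,H,"3,4,5-triOMe",C26H28ClN3O5,1,85,Brown oil,,
6q,6,CH2CH3,H,phenyl,C25H27N3O2,1,40,Brown oil,402.2156,401.2103
6r,6,CH2CH3,H,4-OMe,C26H29N3O3,1,60,Orange oil,432.2271,431.2209
6s,6,CH2CH3,Cl,"3,4-diOMe",C27H30ClN3O4,1,73,Beige solid,496.2019,495.1925
6t,6,CH2CH3,H,"3,4,5-triOMe",C28H33N3O5,1,72,Orange oil,492.2448,491.2420
6u,6,F,H,phenyl,C23H22FN3O2,1,89,Orange oil,392.1917,391.1696
6v,6,F,H,4-OMe,C24H24FN3O3,1,77,Orange oil,422.1874,421.1802
6w,6,F,H,"3,4-diOMe",C25H26FN3O4,1,75,Orange oil,452.1956,451.1907
6x,6,F,H,"3,4,5-triOMe",C26H28FN3O5,1,87,Orange oil,482.2097,481.2013
6y,6,Br,H,phenyl,C23H22BrN3O2,1,95,Beige solid,452.0906,451.0895
6z,6,Br,H,4-OMe,C24H24BrN3O3,1,67,Beige solid,482.1091,481.1001
6aa,6,Br,H,"3,4-diOMe",C25H26BrN3O4,1,70,Orange oil,512.1180,511.1107
6ab,6,Br,H,"3,4,5-triOMe",C26H28BrN3O5,1,43,Orange oil,542.1245,541.1212
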