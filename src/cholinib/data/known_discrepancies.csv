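compound,field,printed,computed,note
5a,esi_2m_na,763,773.4,"[2M+Na]+ printed 763 is inconsistent with 2*M(375.2)+22.99; nominal arithmetic gives 773"
5o,name,"4,5-dimethoxyphenyl","3,4-dimethoxyphenyl","aryl pattern named 4,5-diOMe in the compound name; formula C25H28ClN3O4 matches the 3,4-diOMe grid position"
6u,esi_mh_hr,392.1917,392.1774,"HR [M+H]+ disagrees with the compound's own printed monoisotopic mass 391.1696 + H"
6h,printed_mass,403.48,403.4822,"parenthetical mass is an average molecular weight, not a monoisotopic mass like the other parenthetical values"
6e,esi_adduct,"[M+Cl+Na]+",,"non-standard adduct labels ([M+Cl+Na]+, [2M+2Cl+Na]+); outside the supported adduct grammar"
5n,docking_score_bche,-7.681,-7.861,"the discussion prints both -7.681 and -7.861 kcal/mol for the same 5n/BChE docking score"
5a,esi_fragment,"291 [(M+H)-C4H6NO]+",292,"printed 291 matches loss of the pyrrolidone neutral C4H7NO (85 Da), not the labelled C4H6NO (84 Da)"
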