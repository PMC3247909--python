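sample_id,site,region,year,PUN124_1,PUN124_2,PUN229_1,PUN229_2,PUN935_1,PUN935_2,PUN1157_1,PUN1157_2,PUN132_1,PUN132_2,PUN894_1,PUN894_2
SL49,SPNP,Shey,2008,90,96,106,112,121,121,101/103,103,118,118,110,110
SL54,SPNP,Shey,2008,96,90,102,106,115,119,105,105,112,116,110,110
SL55,SPNP,Shey,2008,96,90,102,106,115,119,105,105,112,116,110,110
SL57,SPNP,Shey,2008,90,92,106,112,121,121,101,101,118,120,110,110
SL64,SPNP,Dho,2008,94,96,102,106,119,121,101,105,118,118,110,110
SL42,KCA,Yagma,2009,96,98,106,110,115,119,103,105,112,118,110,110
SL28,KCA,Gunsa,2009,89,98,106,110,119,123,103,105,112,118,110,118
SL34,KCA,Yagma,2009,-,-,110,112,115,115/119,101/109,109,118,118,110,118
SL25,KCA,Gunsa,2009,96,96,108/110,110,115/119,119,105/101,105,112,112,110,110
SL3,KCA,Gunsa,2006,96,96,110,110,115,119,101,105,112,118,110,110
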