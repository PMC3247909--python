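sample_id,site,region,sex
SL49,SPNP,Shey,FEMALE
SL54,SPNP,Shey,FEMALE
SL55,SPNP,Shey,FEMALE
SL57,SPNP,Shey,MALE
SL64,SPNP,Dho,FEMALE
SL42,KCA,Yagma,MALE
SL34,KCA,Yagma,FEMALE
SL28,KCA,Gunsa,MALE
SL25,KCA,Gunsa,FEMALE
SL3,KCA,Gunsa,FEMALE
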