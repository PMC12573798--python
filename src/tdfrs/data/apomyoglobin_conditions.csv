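label,pH,buffer_label,buffer_conc_mM,helix_pct,helix_sd,delta_ST,delta_ST_sd
pH 6,6,,0,51,1.6,,
"pH 6, 20 mM NaP",6,NaP,20,50,0.5,,
pH 4,4,,0,43,2.1,,
"pH 4, 20 mM NaAc",4,NaAc,20,34,3.2,,
"pH 4, 10 mM NaAc",4,NaAc,10,33,2.2,,
pH 2,2,,0,4,0.3,,
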