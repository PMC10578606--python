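species,locus,state
X_laevis,dmw_exon4,1
X_gilli,dmw_exon4,1
X_petersii,dmw_exon4,1
X_poweri,dmw_exon4,1
X_victorianus,dmw_exon4,1
X_largeni,dmw_exon4,1
X_pygmaeus,dmw_exon4,1
X_itombwensis,dmw_exon4,1
X_kobeli,dmw_exon4,1
X_andrei,dmw_exon4,1
X_vestitus,dmw_exon4,0
X_clivii,dmw_exon4,0
X_muelleri,dmw_exon4,0
X_tropicalis,dmw_exon4,0
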