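# Synthetic example panel of sex-related genes (editable).
# One gene id per line; '#' starts a comment. This is a stand-in list of
# well-known vertebrate sex-differentiation genes (with L/S homeolog
# suffixes as used for allotetraploid Xenopus), NOT the exact published
# 74-gene table, which ships with the original study's supplement.
dmrt1.L
dmrt1.S
foxl2.L
foxl2.S
sox9.L
sox9.S
cyp19a1.L
cyp19a1.S
cyp17a1.L
cyp17a1.S
hsd17b1.L
hsd17b1.S
hsd3b1.L
hsd3b1.S
star.L
star.S
nr5a1.L
nr5a1.S
nr0b1.L
nr0b1.S
wnt4.L
wnt4.S
rspo1.L
rspo1.S
ctnnb1.L
ctnnb1.S
amh.L
amh.S
amhr2.L
amhr2.S
fgf9.L
fgf9.S
fshr.L
fshr.S
esr1.L
esr1.S
esr2.L
esr2.S
ar.L
ar.S
gata4.L
gata4.S
wt1.L
wt1.S
sf3a1.L
sf3a1.S
lhx9.L
lhx9.S
emx2.L
emx2.S
nr6a1.L
nr6a1.S
dhh.L
dhh.S
ptgds.L
ptgds.S
cbx2.L
cbx2.S
map3k1.L
map3k1.S
gadd45g.L
gadd45g.S
fog2.L
fog2.S
dax1.L
dax1.S
sox3.L
sox3.S
piwil1.L
piwil1.S
ddx4.L
ddx4.S
dazl.L
dazl.S
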