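# glycolysis
# Synthetic stand-in list: canonical mouse glycolytic-process genes
# (GO:0006096-style membership). Editable; an externally curated list of
# the same size (85) is a drop-in replacement.
Hk1
Hk2
Hk3
Hkdc1
Gck
Gpi1
Pfkl
Pfkm
Pfkp
Aldoa
Aldob
Aldoc
Tpi1
Gapdh
Gapdhs
Pgk1
Pgk2
Pgam1
Pgam2
Bpgm
Eno1
Eno1b
Eno2
Eno3
Eno4
Pkm
Pklr
Ldha
Ldhb
Ldhc
Ldhal6b
Pfkfb1
Pfkfb2
Pfkfb3
Pfkfb4
Fbp1
Fbp2
Pck1
Pck2
G6pc
G6pc2
G6pc3
Adpgk
Galm
Galk1
Galk2
Galt
Gale
Pgm1
Pgm2
Pgm3
Ugp2
Pdha1
Pdha2
Pdhb
Pdhx
Dlat
Dld
Pdk1
Pdk2
Pdk3
Pdk4
Pdp1
Pdp2
Slc2a1
Slc2a2
Slc2a3
Slc2a4
Slc2a5
Slc16a1
Slc16a3
Slc16a7
Gpd1
Gpd2
Mpc1
Mpc2
Minpp1
Pgp
Hif1a
Tigar
Myc
Egln1
Egln3
Vhl
Prkaa1
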