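# oxphos
# Synthetic stand-in list: canonical mouse oxidative-phosphorylation genes
# (complexes I-V and assembly factors). Editable; an externally curated
# list of the same size (96) is a drop-in replacement.
Ndufa1
Ndufa2
Ndufa3
Ndufa4
Ndufa5
Ndufa6
Ndufa7
Ndufa8
Ndufa9
Ndufa10
Ndufa11
Ndufa12
Ndufa13
Ndufab1
Ndufb2
Ndufb3
Ndufb4
Ndufb5
Ndufb6
Ndufb7
Ndufb8
Ndufb9
Ndufb10
Ndufb11
Ndufs1
Ndufs2
Ndufs3
Ndufs4
Ndufs5
Ndufs6
Ndufs7
Ndufs8
Ndufv1
Ndufv2
Ndufv3
mt-Nd1
mt-Nd2
mt-Nd3
mt-Nd4
mt-Nd4l
mt-Nd5
mt-Nd6
Sdha
Sdhb
Sdhc
Sdhd
Uqcrc1
Uqcrc2
Uqcrfs1
Uqcrb
Uqcrq
Uqcrh
Uqcr10
Uqcr11
Cyc1
mt-Cytb
Cox4i1
Cox4i2
Cox5a
Cox5b
Cox6a1
Cox6a2
Cox6b1
Cox6b2
Cox6c
Cox7a1
Cox7a2
Cox7a2l
Cox7b
Cox7c
Cox8a
Cox8b
mt-Co1
mt-Co2
mt-Co3
Atp5f1a
Atp5f1b
Atp5f1c
Atp5f1d
Atp5f1e
Atp5pb
Atp5pd
Atp5pf
Atp5po
Atp5mc1
Atp5mc2
Atp5mc3
Atp5me
Atp5mf
Atp5mg
mt-Atp6
mt-Atp8
Ndufaf1
Ndufaf2
Sdhaf1
Uqcc1
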