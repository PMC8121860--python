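# lysosomal
# Synthetic stand-in list: mouse lysosomal membrane/hydrolase/V-ATPase genes.
# Editable.
Lamp1
Lamp2
Ctsb
Ctsd
Ctsl
Ctss
Ctsk
Gba
Gla
Hexa
Hexb
Naglu
Atp6v0a1
Atp6v0c
Atp6v1a
Atp6v1b2
Tfeb
Tfe3
Mcoln1
Npc1
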