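# mtdna_replication
# Synthetic stand-in list: 18 core mouse mtDNA replisome / maintenance genes.
# Editable; an externally curated list of the same size is a drop-in
# replacement.
Polg
Polg2
Twnk
Tfam
Tfb2m
Ssbp1
Polrmt
Mgme1
Dna2
Rnaseh1
Lig3
Top1mt
Top3a
Primpol
Tefm
Mterf1a
Fen1
Mpv17
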