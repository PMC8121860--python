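# autophagy
# Synthetic stand-in list: core mouse macroautophagy machinery. Editable.
Atg3
Atg4b
Atg5
Atg7
Atg9a
Atg10
Atg12
Atg13
Atg14
Atg16l1
Atg101
Becn1
Map1lc3a
Map1lc3b
Gabarap
Gabarapl1
Gabarapl2
Sqstm1
Ulk1
Ulk2
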