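gene	abbreviation	in_silico_group	de_gonad
DM domain gene on the Y chromosome / doublesex and mab-3-related transcription factor 1a	dmY/dmrt1a	SD7	up_in_male
Gonadal soma-derived factor	gsdf	SD17	up_in_male
Y chromosome-specific antimuellerian hormone	amhY	SD4	up_in_male
Antimuellerian hormone receptor 2	amhr2	SD1	no_expression
Sexually dimorphic on the Y chromosome	sdY	NA	NA
SRY-box containing protein 3Y	sox3Y	SD18	up_in_female
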