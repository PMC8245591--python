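>integrase_exemplar synthetic stand-in for a tyrosine-integrase-family marker
MDKAVAVRKTFVVRPDNSWTFVFNGTICAKIGNKGKGQYLTLIDGNNDAIGKFWGKTRSP
IEPIAWDLAGKVVFPVTKRPEKQNRKTEYLIAASSSSGEGFGWFTRVKAAEEPEVTVLGK
ETTNEGNRFGRLEFAIEHSSFKKIRRKHANVNGYLERLQQPVPLRVDTILTLWTRLVPLW
TRNVTSVPANINGSLGIVKPVLKDVYHGDDDEVKWKTAPQLDAVLETPDECPDMTYAIRS
>excisionase_exemplar synthetic stand-in for an excisionase-family marker
MESGDGTTIKMKRGLLYHLYGFRPSVAFIIGAPLTVPCYWTYKTNPDLGCLMKSLDGTVG
GRRTSYTTQPGGVTTTGRYDYDANQ
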