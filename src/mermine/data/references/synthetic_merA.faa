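>synthetic_merA_ref synthetic mercuric-reductase-like reference (not BAB62433)
MNKVGGVVDALKQDEKIVLPYEGVARQTCEVFLNQRAGSRKLGLIGLGKEDKDEIANICL
VDSEVKDIKQRNKHRVLKGGMAFFATGKNCAVFVPLCRNSKNSDQRFKSKKDFVVGECTS
NKMTGPLHESDFLYGTMIQVIQPGRIHTVSQSEAARAGEISVMLATAFCTNHPEVIYTNI
GCFNAHVKNEVVLILDVYVSKASFALCNLLLCAIYQSTNWIHTSSTSCSTSEPPPATDPM
TLGNLAQCSDQAYCLLDADSETKYTFAVTSFDMHSGALNVFLFYNIKVVTEHPVTKAVLS
HTNEFTVIQVYKAGAKRASETVTNVGTTSGTRMHSMTLLPTVDADPEPCESTFKLYFEAS
WAPKTTTGSSNAHRSFVDSTTVTTRFAPHSYNTPFYLAHFDDKFTKFNYDYVDHNLKAVQ
HNQKDNSADNGVVERQAAKEKSVKACYLRPNADRLFAWGYSSELEELERQIELRQAQLDG
TFGESTGKYCSIKDEFTCKQERPIAINRTCGSLKPSDPMESPTSASIPAYFHPKLKAVLF
RVEEDFGLANDSYQDTGGFLIVQNFDCVYTPKVLGVEPSKKKLKTTEQGAEYFVDFCGFQ
QHSDYQEFDVGGRLKDVPLAFWPIPDECCCV
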