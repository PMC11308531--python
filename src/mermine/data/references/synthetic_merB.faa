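>synthetic_merB_ref synthetic organomercurial-lyase-like reference (not P77072)
MCQVCITNQQAELPFTYLGSAADVSWGTGQHVRPGKDDRALSLTSITPGLLGIWFRRHVE
PYFQSQGGAISESLTAAATFQVLSLTGTMVALYDSSETTLKSSRYLCLGSKNHAYSEKLR
RSTGWPSNLASFWKVKCTTSNDSKTIKDYPVTATRMTQCGQSKCTKDHCWVASDVALEGD
STVVPITATAGADCPPASPGSCPGAKRYFNSY
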