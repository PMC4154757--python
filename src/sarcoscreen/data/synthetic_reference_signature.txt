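# Synthetic stand-in reference prognostic signature (gene symbols).
# A fixture list of mitosis / chromosome-integrity genes used only for
# overlap classification in venn_classify; it is NOT a reproduction of any
# published signature.
PTTG1
ASPM
CDC20
KIF20A
AURKA
AURKB
BIRC5
BUB1
BUB1B
CCNA2
CCNB1
CCNB2
CENPA
CENPE
CEP55
ECT2
ESPL1
FOXM1
KIF2C
KIF4A
MELK
NDC80
PLK1
PRC1
RRM2
SPAG5
TOP2A
TPX2
TTK
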