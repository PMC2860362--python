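# 24 GO Biological Process terms expected to respond to osteogenic
# differentiation of mesenchymal stem cells; the reference list used for
# ROC evaluation of class rankings (one GO id per line, description free).
GO:0007050 cell cycle arrest
GO:0009653 morphogenesis
GO:0001558 regulation of cell growth
GO:0045786 negative regulation of progression through cell cycle
GO:0016055 Wnt receptor signaling pathway
GO:0008284 positive regulation of cell proliferation
GO:0016049 cell growth
GO:0009790 embryonic development
GO:0007178 transmembrane receptor protein serine/threonine kinase signaling pathway
GO:0001501 skeletal development
GO:0000188 inactivation of MAPK activity
GO:0030111 regulation of Wnt receptor signaling pathway
GO:0045595 regulation of cell differentiation
GO:0001503 ossification
GO:0000187 activation of MAPK activity
GO:0000165 MAPKKK cascade
GO:0043406 positive regulation of MAPK activity
GO:0030198 extracellular matrix organization and biogenesis
GO:0050793 regulation of development
GO:0007179 transforming growth factor beta receptor signaling pathway
GO:0042127 regulation of cell proliferation
GO:0040007 growth
GO:0051216 cartilage development
GO:0000902 cellular morphogenesis
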