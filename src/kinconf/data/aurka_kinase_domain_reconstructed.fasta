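>AURKA_HUMAN|O14965|kinase-domain|start=127 reconstructed reference profile; sequence compiled from published residue annotations (55 position->residue anchors verified); not a verbatim database download
QWALEDFEIGRPLGKGKFGNVYLAREKQSKFILALKVLFKAQLEKAGVEHQLRREVEIQS
HLRHPNILRLYGYFHDATRVYLILEYAPLGTVYRELQKLSKFDEQRTATYITELANALSY
CHSKRVIHRDIKPENLLLGSAGELKIADFGWSVHAPSSRRTTLCGTLDYLPPEMIEGRMH
DEKVDLWSLGVLCYEFLVGKPPFEANTYQETYKRISRVEFTFPDFVTEGARDLISRLLKH
NPSQRPMLREVLEHPWITANSS
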