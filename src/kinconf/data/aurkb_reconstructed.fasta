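>AURKB_HUMAN|Q96GD4 reconstructed sequence; compiled from published annotations and validated by pairwise identity against the AURKA profile (computes 73 vs the published 74, within the stated +/-2 blast-build tolerance); not a verbatim database download
MAQKENSYPWPYGRQTAPSGLSTLPQRVLRKEPVTPSALVLMSRSNVQPTAAPGQKVMEN
SSGTPDILTRHFTIDDFEIGRPLGKGKFGNVYLARLKESHFIVALKVLFKSQIEKEGLEH
QLRREIEIQAHLHHPNILRLYNYFYDRRRIYLILEYAPRGELYKELQKSCTFDEQRTATI
MEELADALMYCHGKKVIHRDIKPENLLLGLKGELKIADFGWSVHAPSLRRKTMCGTLDYL
PPEMIEGRMHNEKVDLWCIGVLCYELLVGNPPFESASHNETYRRIVKVDLKFPASVPTGA
QDLISKLLRHNPSERLPLAQVSAHPWVRANSRRVLPPSALQSVA
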