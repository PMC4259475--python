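# kinconf binding-site sub-pocket / hot-spot mapping, version 1
# RECONSTRUCTED mapping: the pocket partition (AP adenine, BP back [synonym HPI],
# RP ribose, PP phosphate, SP solvent, HPII hydrophobic allosteric) is standard;
# hot-spot membership has no unique machine-readable definition, so the
# assignment below is a reconstruction and is user-overridable by pointing the
# API/CLI at an edited copy of this file.
#
# section: bit_pocket  (fingerprint bit -> sub-pocket)
bit_pocket	1	BP
bit_pocket	2	AP
bit_pocket	3	AP
bit_pocket	4	AP
bit_pocket	5	SP
bit_pocket	6	RP
bit_pocket	7	PP
bit_pocket	8	PP
bit_pocket	9	HPII
bit_pocket	10	HPII
bit_pocket	11	HPII
bit_pocket	12	HPII
bit_pocket	13	HPII
bit_pocket	14	PP
#
# section: pocket_residues  (sub-pocket -> canonical residue anchors)
pocket_residues	AP	L210,E211,Y212,A213,G216
pocket_residues	BP	L210,E181,K162
pocket_residues	RP	A273,G276
pocket_residues	PP	E181,D274,F144,K141,K143
pocket_residues	SP	P214,L215,G216,T217,R220
pocket_residues	HPII	F275,W277,V279,H280,K162
#
# section: hotspot  (index -> pocket ; fingerprint bits ; interaction kinds)
hotspot	1	BP	1	HBOND
hotspot	2	AP	2,3,4	HBOND
hotspot	3	SP	5	HBOND
hotspot	4	PP	7	HBOND
hotspot	5	HPII	10,11	CATION_PI,PI_PI
hotspot	6	RP	6,8	HBOND
hotspot	7	HPII	9,12,13,14	HBOND,PI_PI,CH_PI
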