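# Methods

## Canonical numbering and the reference profile

All motif residues are addressed in canonical AURKA_HUMAN (UniProt O14965)
positions, 1-based. A chain is mapped by global Needleman–Wunsch alignment
(BLOSUM62, gap open 11 / extend 1, free end gaps) of its one-letter sequence
against the bundled kinase-domain reference profile (positions 127–388);
percent identity uses Smith–Waterman local alignment with the same scoring and
the blast-p convention — identical pairs divided by alignment length including
gap columns, ×100, rounded to integer. A ±2-point band should be allowed when
comparing identities across alignment implementations, since the exact
extension and composition adjustments of any given blast build differ.

The mapping is injective; anchors (K162, E181, GK=L210 and the GK+n hinge
ladder, A273–G276, W277, V279, H280, T288, the G-loop residues 136–148, Q177,
Q185, H254, R255, R180) are reported only where their canonical column
actually aligned — an unaligned anchor is absent, never guessed. Chains
covering less than 30% of the profile are rejected as not recognisably
kinase-domain-like.

The bundled profile file is a *reconstruction*: it was compiled from published
per-position residue annotations of the Aurora-A kinase domain and verified
programmatically against 55 independent position→residue constraints (every
anchor above plus the hinge, catalytic-loop, A-loop and G-loop rosters); the
bundled AURKB sequence is likewise reconstructed and validated by its pairwise
identity against the profile (computes 73 vs the published 74). The file
headers say so. When network access is available both should be replaced by
verbatim UniProt records; none of the geometric machinery depends on the
filler residues between anchors.

## Centre-of-mass metrics

The default COM rule is mass-weighted side-chain heavy atoms with a Cα
fallback for glycine; all-heavy-atom and Cα-only selections and unit
weighting are selectable diagnostics. Distances are Euclidean (Å), angles in
degrees in [0, 180], dihedrals IUPAC-signed in (−180, 180].

Inter-motif parameters: r2(GK⋯E181), r3(GK⋯F275), r4(K162⋯F275),
r6(K162⋯E181), ∡K(GK+2)E, ∡K(GK+2)F, ∡E(GK)F, plus r5(E181⋯F275) which is
computed but treated as diagnostic because it varies little between
conformations. Intra-motif parameters:
r1(A273⋯D274), r2(D274⋯F275), r3(F275⋯G276), r4(D274⋯G276), r5(F275⋯W277),
r6(F275⋯T288), ∡DFG (vertex F275), ∡FWH and ∡FWT (vertex W277).

## Classification and calibration

The discriminative parameter subsets are fixed — inter {r2, r3, r4, r6,
∡E(GK)F} and intra {r5, r6, ∡DFG, ∡FWH} — and the decision rule is explicit
and fully reproducible rather than an opaque fitted model: nearest centroid in the 9-dimensional
z-scored discriminative subspace, calibrated from any labelled reference set
(`calibrate()`); the margin reported with each call is the distance gap to the
second-best class, and exact ties break toward DFG-in, the most populous
class. An αC in/out boundary on r6(K162⋯E181) and the two G-loop thresholds
are calibrated as midpoints between the class means of the references, with
fallback defaults (6.0 Å; 60°; 6.0 Å) when a class is unrepresented.

The default calibration ships as *code, not numbers*: it is rebuilt
deterministically at import time from the twelve noise-free synthetic fixtures
(all DFG × αC × G-loop label combinations), so there is no stored constant
that can drift from the generator. Calibrations are serialisable to a
versioned key=value text file and a user can calibrate from real labelled
structures instead (e.g. the 3E5A / 3UNZ / 2J4Z crystal-structure references),
which is the route for reproducing crystal-structure label tables when the
entries can be downloaded.

The αC call is decided by r6 against the calibrated boundary; E181 i→i±4
Cα distances (to Q177/Q185) are reported as helix-geometry diagnostics but are
not decisive. The G-loop is FOLDED only when *both* the mean circular (φ,ψ)
deviation of residues 139–147 from the β-sheet reference (−140°, 135°) exceeds
its threshold *and* the F144 side-chain COM sits closer to the ATP-site
centroid (mean COM of GK, GK+3, K162, A273) than the displacement threshold;
requiring both prevents either pure backbone distortion or incidental F144
proximity from triggering the call alone. A G-loop span more than half
missing is an error, not a guess.

## Interaction criteria

No single canonical cutoff set exists for these interaction classes, so the
defaults follow common SIFt practice and are all user-overridable and
recorded in output headers: strong H-bond D⋯A ≤ 3.5 Å (D–H⋯A ≥ 120° when the
hydrogen direction is inferable), weak C–H⋯O/N C⋯A ≤ 3.8 Å from aromatic
carbons, salt bridge ≤ 4.0 Å between opposite formal charges, cation-π ≤
6.0 Å with ≤ 30° off the ring normal, π-π face ≤ 5.5 Å at ≤ 30° interplanar
or edge 4.5–6.5 Å at 60–90°, CH-π ≤ 4.5 Å at ≥ 30° elevation, van der Waals
at the radius sum + 0.5 Å (recorded but never fingerprinted).

Crystal structures lack hydrogens, so backbone amide H positions are
idealised from N, CA and the preceding carbonyl carbon; rotatable side-chain
donors (Lys NZ, Ser/Thr/Tyr OH, …) fall back to a distance-only criterion and
the record subtype carries a `no-angle` flag. Histidine protonation is
ambiguous and His is treated as donor, acceptor and aromatic simultaneously.
Ligand pharmacophore typing is rule-based from heavy atoms only (bond
inference by covalent-distance cutoffs, ring planarity by SVD): this is
deliberate — template-free bond-order perception on HETATM records is
unreliable — and it is sufficient for the fragment chemistry the fixtures
exercise, but it will under-type exotic ligand chemotypes; for those, typed
features can be supplied directly on a `LigandPose`.

## The 14-bit fingerprint

Bits are (canonical residue, interaction kind, ligand feature role) triples;
HD/HA name the *ligand* role. Only strong H-bonds key the H-bond bits. Three
bit conventions require disambiguation and are fixed as follows: bit 4 (A213)
takes the ligand-acceptor role, because the hinge alanine donates its
backbone N–H in the large majority of complexes; bit 8 (D274) is an H-bond
from a ligand donor to the aspartate side-chain carboxylate (a hydrophobic
feature cannot make an H-bond); bit 11's aromatic partner is the canonical
DFG phenylalanine F275 (169 is the equivalent position in the p38 numbering
sometimes quoted for this interaction). Bit 3 (Y212) counts both backbone and
side-chain hydroxyl acceptor routes, with the subtype recording which fired.

## Sub-pockets and hot-spots

The six-pocket partition (AP adenine, BP back — synonym HPI, RP ribose, PP
phosphate, SP solvent, HPII hydrophobic allosteric) is standard; hot-spot
membership has no unique machine-readable definition. The shipped
`subpockets.tsv` is therefore labelled *reconstructed*: bits 2–4 form the hinge hot-spot (2), bit
1 the back-pocket hot-spot (1), bit 5 the solvent-edge hot-spot (3), bit 7
the αC hot-spot (4), bits 10–11 the allosteric aromatic hot-spot (5), bits
6+8 the DFG H-bond hot-spot (6) and bits 9+12–14 the A-loop/G-loop aromatic
hot-spot (7). The file is versioned and user-overridable; class matching
(type I {2,3}, I½ {1,2,6}, II {2,3,4,5,6,7}, III {5,6,7}) scores the covered
fraction of required hot-spots and zeroes a class whose DFG/αC requirement
conflicts with the observed conformation.

## Synthetic fixtures

The generator builds only what the metrics measure: G-loop (132–152), β3
strand (156–168), αC helix (173–190), hinge (205–222), catalytic loop
(250–260) and DFG/A-loop (269–292) segments in a common frame, with author
numbering equal to canonical numbering and sequences taken from the reference
profile, so the closed loop exercises the real alignment-based mapping. The
G-loop is built residue-by-residue from ideal internal coordinates (N–CA
1.458, CA–C 1.525, C–N 1.329 Å, ω = 180°), giving exact φ/ψ control: the
extended state is uniformly (−140°, 135°), the folded state curls residues
140–146 to (−70°, −40°) and drops the F144 aim point toward the ATP-site
centroid. Other segments are Cα bead paths (~3.5 Å spacing) with locally
ideal N/C/O geometry and strand-like side alternation; side chains are placed
from per-residue templates so their mass-weighted COM lands on the chosen aim
ray. Class geometry honours the qualitative descriptions of the three DFG
states (in: K162–E181 ion pair intact, F275 packed below E181; out-up: loop
parallel to the helix, F275 above E181, D274 in the polar Q185/R255
environment; out: D274 dropped into the C-lobe opposite F275).

Toy complexes place small chemically sensible fragments (secondary amines,
carbonyls, benzenes, carboxylates) at mid-window geometry for each requested
fingerprint bit, steering ring placements through a maximin clearance score
against every protein ring, cation centre and already-placed fragment so that
no unrequested bit fires. An audit list of intended (bit, residue, kind)
triples accompanies each complex for oracle comparison.

What the fixtures do **not** emulate: covalent continuity between segments,
packing, solvent, crystallographic disorder, real ligand topology, or the
actual population of conformations in the PDB. Passing the closed-loop tests
therefore demonstrates that the metrics, decision rules and detectors are
self-consistent and noise-tolerant under the stated geometry — not that the
default synthetic calibration reproduces crystal-structure label counts; that
requires calibrating on real labelled references, which is supported but
needs the entries to be available.

## Numerical choices and degenerate inputs

Coordinates are Å throughout; PDB output carries three decimals, so
round-trips are exact to 5×10⁻⁴ Å. Alt-locs keep the highest occupancy (ties
prefer 'A'); multi-model files default to MODEL 1. Modified residues
TPO/MSE/PTR/CME are renamed to their parents with non-parent atoms dropped
and provenance retained on the residue. Zero-length angle arms, missing
backbone atoms, absent anchors and chains below alignment coverage raise
errors naming the offending item rather than guessing. Classification noise
tolerance was validated at σ = 0.3 Å i.i.d. coordinate noise, 200 seeds per
label combination (problem sizes chosen so the whole validation runs in
minutes on one core).

## Known limitations

* The default calibration encodes the synthetic fixture geometry; real
  structures should be classified with a calibration built from real labelled
  references.
* Ligand typing is heuristic and heavy-atom-only; donors/acceptors on unusual
  heterocycles may be missed.
* Weak H-bond detection considers aromatic-carbon donors only, and side-chain
  donor directionality is not modelled.
* The hot-spot mapping is a reconstruction and should be edited when better
  ground truth is available.
* Multi-chain structures are classified one chain at a time; no quaternary
  reasoning.
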