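"""Map kinase chains onto canonical Aurora-A (AURKA_HUMAN) numbering.

Motif residues -- the beta3 lysine K162, the alphaC glutamate E181, the
gatekeeper L210 with its hinge offsets GK+1..GK+10, the DFG motif 274-276, the
activation loop through T288 and the glycine-rich loop 136-148 -- are
addressed uniformly through a :class:`ResidueMap` built by global alignment of
a chain's sequence against the bundled reference profile.  Percent identity
between two sequences follows the blast-p convention: identical pairs over the
length of the best local alignment (Smith-Waterman, BLOSUM62, gap 11/1).

Canonical numbering is the UniProt O14965 position, 1-based.  The bundled
profile covers the kinase domain (127-388); it is a reconstruction verified
against the published residue roster (see the file header and docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import Residue, Structure, THREE_TO_ONE

__all__ = [
    "ReferenceProfile", "ResidueMap", "load_reference_profile",
    "align_to_reference", "build_residue_map", "locate_gatekeeper",
    "pairwise_identity", "read_fasta", "ANCHOR_POSITIONS", "MOTIF_SPANS",
]

# named anchors -> canonical AURKA position
ANCHOR_POSITIONS: dict[str, int] = {
    "K162": 162, "E181": 181,
    "GK": 210, "GK+1": 211, "GK+2": 212, "GK+3": 213, "GK+4": 214,
    "GK+5": 215, "GK+6": 216, "GK+7": 217, "GK+10": 220,
    "A273": 273, "D274": 274, "F275": 275, "G276": 276,
    "W277": 277, "V279": 279, "H280": 280, "T288": 288,
    "F144": 144, "L139": 139, "K141": 141, "G142": 142, "K143": 143,
    "G145": 145, "Q177": 177, "Q185": 185,
    "R255": 255, "R180": 180, "H254": 254,
}

# motif spans in canonical numbering (inclusive); the DFG motif is the
# N-terminal boundary of the A-loop by convention, so the two overlap there.
MOTIF_SPANS: dict[str, tuple[int, int]] = {
    "g_loop": (136, 148),
    "alpha_c": (175, 189),
    "hinge": (208, 220),
    "dfg": (274, 276),
    "a_loop": (274, 288),
}


@dataclass(frozen=True)
class ReferenceProfile:
    sequence: str
    start: int  # canonical position of sequence[0]
    anchors: dict[str, int] = field(default_factory=lambda: dict(ANCHOR_POSITIONS))
    motif_spans: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(MOTIF_SPANS))

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1

    def residue_at(self, canonical: int) -> str:
        return self.sequence[canonical - self.start]


@dataclass
class ResidueMap:
    """Injective mapping author residue -> canonical AURKA position for one chain."""

    chain_id: str
    author_to_canonical: dict[tuple[int, str], int]
    anchors: dict[str, tuple[int, str]]  # anchor name -> author key, only where aligned
    coverage: float
    identity: float = 0.0

    def canonical_of(self, author_number: int, icode: str = "") -> int | None:
        return self.author_to_canonical.get((author_number, icode))

    def author_of(self, canonical: int) -> tuple[int, str] | None:
        for key, pos in self.author_to_canonical.items():
            if pos == canonical:
                return key
        return None

    def anchor_residue(self, s: Structure, name: str) -> Residue:
        if name not in self.anchors:
            raise KeyError(f"anchor {name} not aligned in chain {self.chain_id}")
        num, icode = self.anchors[name]
        res = s.residue(self.chain_id, num, icode)
        if res is None:
            raise KeyError(f"anchor {name}: residue {num}{icode} missing from chain {self.chain_id}")
        return res

    def to_tsv(self) -> str:
        rev_anchor = {v: k for k, v in self.anchors.items()}
        lines = ["chain\tauthor_number\tcanonical_position\tanchor_label"]
        for (num, icode), pos in sorted(self.author_to_canonical.items(), key=lambda kv: kv[1]):
            label = rev_anchor.get((num, icode), "")
            lines.append(f"{self.chain_id}\t{num}{icode}\t{pos}\t{label}")
        return "\n".join(lines) + "\n"


def read_fasta(text: str) -> dict[str, str]:
    """Minimal FASTA reader returning {header: sequence}."""
    seqs: dict[str, str] = {}
    header = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            header = line[1:]
            seqs[header] = ""
        elif header is not None:
            seqs[header] += line
    return seqs


def load_reference_profile() -> ReferenceProfile:
    """Load the bundled AURKA kinase-domain reference profile."""
    text = (
        resources.files("kinconf.data")
        .joinpath("aurka_kinase_domain_reconstructed.fasta")
        .read_text()
    )
    seqs = read_fasta(text)
    header, sequence = next(iter(seqs.items()))
    start = 1
    for tok in header.split():
        for part in tok.split("|"):
            if part.startswith("start="):
                start = int(part.split("=", 1)[1])
    return ReferenceProfile(sequence=sequence, start=start)


def load_bundled_sequence(name: str) -> str:
    """Load another bundled sequence (e.g. 'aurkb') by short name."""
    text = (
        resources.files("kinconf.data").joinpath(f"{name}_reconstructed.fasta").read_text()
    )
    return next(iter(read_fasta(text).values()))


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # free end gaps: chains are fragments of the full-length protein
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_to_reference(
    chain_sequence: str,
    profile: ReferenceProfile | None = None,
    min_coverage: float = 0.3,
) -> tuple[list[int | None], float, float]:
    """Globally align a chain sequence to the reference profile.

    Returns (canonical position per sequence index or None, coverage, identity
    fraction over aligned columns).  Raises ``ValueError`` when fewer than
    ``min_coverage`` of the reference positions align -- the chain is then not
    a recognisable kinase domain.
    """
    if profile is None:
        profile = load_reference_profile()
    if len(chain_sequence) < 50:
        raise ValueError("sequence too short to map (need >= 50 residues)")
    aln = _global_aligner().align(profile.sequence, chain_sequence)[0]
    mapping: list[int | None] = [None] * len(chain_sequence)
    aligned_ref = 0
    ident = 0
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            mapping[q0 + k] = profile.start + r0 + k
            aligned_ref += 1
            if profile.sequence[r0 + k] == chain_sequence[q0 + k]:
                ident += 1
    coverage = aligned_ref / len(profile.sequence)
    if coverage < min_coverage:
        raise ValueError(
            f"not a recognizable kinase domain (coverage {coverage:.2f} < {min_coverage})"
        )
    identity = ident / aligned_ref if aligned_ref else 0.0
    return mapping, coverage, identity


def build_residue_map(
    s: Structure,
    chain_id: str | None = None,
    profile: ReferenceProfile | None = None,
) -> ResidueMap:
    """Build the author->canonical mapping for one chain of a structure."""
    if profile is None:
        profile = load_reference_profile()
    if chain_id is None:
        chain_id = s.first_chain_id()
    residues = s.chain(chain_id)
    seq = "".join(THREE_TO_ONE.get(r.name, "X") for r in residues)
    mapping, coverage, identity = align_to_reference(seq, profile)
    author_to_canonical = {
        residues[i].author_key: pos for i, pos in enumerate(mapping) if pos is not None
    }
    canonical_to_author = {pos: key for key, pos in author_to_canonical.items()}
    anchors = {
        name: canonical_to_author[pos]
        for name, pos in profile.anchors.items()
        if pos in canonical_to_author
    }
    return ResidueMap(
        chain_id=chain_id,
        author_to_canonical=author_to_canonical,
        anchors=anchors,
        coverage=coverage,
        identity=identity,
    )


def locate_gatekeeper(m: ResidueMap, s: Structure) -> tuple[int, str]:
    """(author number, residue name) of the residue aligned to canonical 210."""
    if "GK" not in m.anchors:
        raise KeyError("gatekeeper anchor not aligned in this chain")
    res = m.anchor_residue(s, "GK")
    return res.author_number, res.name


def pairwise_identity(seq_a: str, seq_b: str) -> int:
    """blast-p style percent identity of the best local alignment, rounded.

    Identical aligned pairs divided by alignment length (gap columns included),
    times 100.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_a == seq_b:
        return 100
    aln = _local_aligner().align(seq_a, seq_b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ident = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return round(100.0 * ident / len(s1))
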