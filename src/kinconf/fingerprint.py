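"""The 14-bit structure interaction fingerprint (SIFt) and its comparisons.

Each bit encodes one (binding-site residue, interaction kind, ligand feature
role) triple.  Bits 1-9 are hydrogen bonds to the hinge, alphaC and DFG/A-loop
residues; bit 10 is the K162 cation-pi; bits 11-14 are pi-stacking against the
F275, W277, H280 and F144 aromatic systems.  HD/HA denote the LIGAND feature
role (donor/acceptor); the residue side of each bit is fixed by its
definition.  Only strong hydrogen bonds key the H-bond bits; weak C-H bonds
are reported in interaction tables but never fingerprinted.

Two bit conventions require disambiguation, resolved here and documented in
docs/methods.md: bit 4 (A213) takes the ligand
acceptor role -- the hinge alanine donates its backbone amide N-H in the large
majority of complexes -- and bit 8 (D274) is an H-bond from a ligand donor to
the aspartate side-chain carboxylate.  Bit 11's aromatic partner is the
canonical DFG phenylalanine F275.
"""

from __future__ import annotations

from dataclasses import dataclass

from .canonical_numbering import ResidueMap
from .interactions import InteractionRecord

__all__ = ["BIT_DEFINITIONS", "Fingerprint14", "compute_sift", "tanimoto",
           "frequency_profile"]


@dataclass(frozen=True)
class BitDefinition:
    bit: int                  # 1-based
    canonical: int            # canonical AURKA position of the residue
    label: str
    kind: str                 # interaction kind required
    ligand_role: str          # required ligand feature role


BIT_DEFINITIONS: tuple[BitDefinition, ...] = (
    BitDefinition(1, 210, "GK L210", "HBOND_STRONG", "HD"),
    BitDefinition(2, 211, "GK+1 E211", "HBOND_STRONG", "HD"),
    BitDefinition(3, 212, "GK+2 Y212", "HBOND_STRONG", "HA"),
    BitDefinition(4, 213, "GK+3 A213", "HBOND_STRONG", "HA"),
    BitDefinition(5, 216, "GK+6 G216", "HBOND_STRONG", "HD"),
    BitDefinition(6, 273, "A273", "HBOND_STRONG", "HD"),
    BitDefinition(7, 181, "alphaC E181", "HBOND_STRONG", "HD"),
    BitDefinition(8, 274, "DFG D274", "HBOND_STRONG", "HD"),
    BitDefinition(9, 280, "A-loop H280", "HBOND_STRONG", "HA"),
    BitDefinition(10, 162, "K162 cation-pi", "CATION_PI", "Ar"),
    BitDefinition(11, 275, "DFG F275 pi-pi", "PI_PI", "Ar"),
    BitDefinition(12, 277, "A-loop W277 pi-pi", "PI_PI", "Ar"),
    BitDefinition(13, 280, "A-loop H280 pi-pi", "PI_PI", "Ar"),
    BitDefinition(14, 144, "G-loop F144 pi-pi", "PI_PI", "Ar"),
)


@dataclass(frozen=True)
class Fingerprint14:
    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != 14:
            raise ValueError("fingerprint must have exactly 14 bits")

    @classmethod
    def from_string(cls, s: str) -> "Fingerprint14":
        return cls(tuple(c == "1" for c in s.strip()))

    @classmethod
    def from_set(cls, on_bits: set[int]) -> "Fingerprint14":
        return cls(tuple((b + 1) in on_bits for b in range(14)))

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    def on_bits(self) -> set[int]:
        return {i + 1 for i, b in enumerate(self.bits) if b}

    def labelled(self) -> str:
        lines = ["bit\tlabel\tset"]
        for d in BIT_DEFINITIONS:
            lines.append(f"{d.bit}\t{d.label}\t{1 if self.bits[d.bit - 1] else 0}")
        return "\n".join(lines) + "\n"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _record_matches(rec: InteractionRecord, d: BitDefinition) -> bool:
    if rec.kind != d.kind or rec.canonical != d.canonical:
        return False
    return rec.ligand_role == d.ligand_role


def compute_sift(
    table: list[InteractionRecord], m: ResidueMap | None = None
) -> Fingerprint14:
    """Encode an interaction table into the 14-bit fingerprint.

    Records must carry canonical residue labels (as produced by
    ``interaction_table`` with a residue map); passing ``m`` fills them in
    for records that lack one.  Records matching no bit are ignored;
    duplicates are idempotent.
    """
    if m is not None:
        for rec in table:
            if rec.canonical is None and rec.chain_id == m.chain_id:
                rec.canonical = m.canonical_of(rec.author_number)
    on = {
        d.bit
        for d in BIT_DEFINITIONS
        if any(_record_matches(rec, d) for rec in table)
    }
    return Fingerprint14.from_set(on)


def tanimoto(a: Fingerprint14, b: Fingerprint14) -> float:
    """|a AND b| / |a OR b|; 1.0 when both fingerprints are empty."""
    inter = sum(1 for x, y in zip(a.bits, b.bits) if x and y)
    union = sum(1 for x, y in zip(a.bits, b.bits) if x or y)
    return 1.0 if union == 0 else inter / union


def frequency_profile(fps: list[Fingerprint14]) -> list[float]:
    """Per-bit set frequency in percent (0-100) across a fingerprint list."""
    if not fps:
        return [0.0] * 14
    n = len(fps)
    return [100.0 * sum(fp.bits[i] for fp in fps) / n for i in range(14)]
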