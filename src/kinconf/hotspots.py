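"""Binding-site sub-pockets, specificity hot-spots and inhibitor-class matching.

The Aurora kinase active site partitions into six sub-pockets -- adenine (AP),
back (BP, synonym HPI), ribose (RP), phosphate (PP), solvent (SP) and the
hydrophobic allosteric pocket (HPII) exposed by the DFG flip.  Seven hot-spots
(sub-pocket regions whose interactions confer target specificity) map onto the
fingerprint bits.  Hot-spot membership is not uniquely defined by any
machine-readable source, so the shipped mapping file is labelled
reconstructed and any edited copy can be supplied instead.

Inhibitor classes follow the standard typology: type I (ATP site, DFG-in),
type I1/2 (ATP site plus gatekeeper back pocket, DFG-in), type II (ATP plus
allosteric, DFG-out) and type III (purely allosteric, DFG-out).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .conformation import ConformationCall
from .fingerprint import Fingerprint14

__all__ = ["SubpocketMap", "ClassProfile", "load_subpocket_map",
           "assign_subpockets", "suggest_class", "CLASS_PROFILES"]

POCKETS = ("AP", "BP", "RP", "PP", "SP", "HPII")


@dataclass
class SubpocketMap:
    bit_pocket: dict[int, str]                    # fingerprint bit -> pocket
    pocket_residues: dict[str, tuple[str, ...]]   # pocket -> canonical anchors
    hotspots: dict[int, tuple[str, tuple[int, ...], tuple[str, ...]]]
    # hot-spot index -> (pocket, fingerprint bits, interaction kinds)
    version: str = "1"

    def __post_init__(self) -> None:
        if set(self.bit_pocket) != set(range(1, 15)):
            raise ValueError("bit->pocket mapping must cover all 14 bits")
        if len(self.hotspots) != len(set(self.hotspots)):
            raise ValueError("hot-spot indices must be unique")


def load_subpocket_map(text: str | None = None) -> SubpocketMap:
    """Parse the sub-pocket mapping table (bundled file by default)."""
    if text is None:
        text = resources.files("kinconf.data").joinpath("subpockets.tsv").read_text()
    bit_pocket: dict[int, str] = {}
    pocket_residues: dict[str, tuple[str, ...]] = {}
    hotspots: dict[int, tuple[str, tuple[int, ...], tuple[str, ...]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        section = fields[0]
        if section == "bit_pocket":
            bit_pocket[int(fields[1])] = fields[2]
        elif section == "pocket_residues":
            pocket_residues[fields[1]] = tuple(fields[2].split(","))
        elif section == "hotspot":
            hotspots[int(fields[1])] = (
                fields[2],
                tuple(int(b) for b in fields[3].split(",")),
                tuple(fields[4].split(",")),
            )
    return SubpocketMap(bit_pocket=bit_pocket, pocket_residues=pocket_residues,
                        hotspots=hotspots)


def assign_subpockets(
    fp: Fingerprint14, pocket_map: SubpocketMap | None = None
) -> dict[str, int]:
    """Coverage count per sub-pocket from the set fingerprint bits."""
    if pocket_map is None:
        pocket_map = load_subpocket_map()
    coverage = {}
    for bit in fp.on_bits():
        pocket = pocket_map.bit_pocket[bit]
        coverage[pocket] = coverage.get(pocket, 0) + 1
    return coverage


@dataclass(frozen=True)
class ClassProfile:
    """One row of the inhibitor-class design table."""

    name: str
    dfg: tuple[str, ...]       # allowed DFG states
    alpha_c: tuple[str, ...]
    pockets: tuple[str, ...]
    hotspots: tuple[int, ...]
    features: tuple[str, ...]


CLASS_PROFILES: tuple[ClassProfile, ...] = (
    ClassProfile("I", ("IN",), ("IN",), ("AP", "SP"), (2, 3),
                 ("HD1", "HA2", "HD2", "HD3", "Ar1")),
    ClassProfile("I1/2", ("IN",), ("IN",), ("BP", "AP", "RP", "PP"), (1, 2, 6),
                 ("HA1", "HD1", "HA2", "HD2", "Ar1", "L", "HD4", "HA3")),
    ClassProfile("II", ("OUT", "OUT_UP"), ("OUT",), ("AP", "RP", "PP", "HPII"),
                 (2, 3, 4, 5, 6, 7),
                 ("HD1", "HA2", "HD2", "Ar1", "L", "HD4", "HA3", "Ar2")),
    ClassProfile("III", ("OUT", "OUT_UP"), ("OUT",), ("PP", "HPII"), (5, 6, 7),
                 ("HD4", "HA3", "Ar2")),
)


def covered_hotspots(
    fp: Fingerprint14, pocket_map: SubpocketMap | None = None
) -> set[int]:
    if pocket_map is None:
        pocket_map = load_subpocket_map()
    on = fp.on_bits()
    return {idx for idx, (_, bits, _) in pocket_map.hotspots.items()
            if any(b in on for b in bits)}


def suggest_class(
    call: ConformationCall | None,
    fp: Fingerprint14,
    pocket_map: SubpocketMap | None = None,
) -> list[tuple[ClassProfile, float]]:
    """Rank inhibitor classes by hot-spot coverage, gated by conformation.

    Score = fraction of the class's required hot-spots covered by the
    fingerprint, zeroed when the observed DFG/alphaC state conflicts with the
    class requirement.  Passing ``call=None`` skips the conformational gate.
    """
    covered = covered_hotspots(fp, pocket_map)
    ranked = []
    for profile in CLASS_PROFILES:
        score = len(covered & set(profile.hotspots)) / len(profile.hotspots)
        if call is not None and (call.dfg not in profile.dfg
                                 or call.alpha_c not in profile.alpha_c):
            score = 0.0
        ranked.append((profile, score))
    ranked.sort(key=lambda pair: -pair[1])
    return ranked
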