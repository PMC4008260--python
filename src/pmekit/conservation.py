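"""Structure-anchored conserved-residue profiling.

Each family member is mapped onto a structural reference by global pairwise
alignment (BLOSUM62, affine gaps) and scored against a curated panel of
functionally important residues.  Conservation is class-aware: catalytic,
stabilizer, cysteine and orientation positions demand identity, while
substrate-binding aromatic positions accept any aromatic residue, and the
polar-interactor / acidic-patch / hydrophobic-bundle positions accept any
residue of the corresponding chemical class ("similarity, not necessarily
identity").

The default panels ship with synthetic stand-in reference sequences that place
the documented panel residues at their published positions (tomato PME
numbering for PMEs, mature kiwi PMEI numbering for PMEIs).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import io as pio

GAP = "-"

#: Residue sets defining "conserved" per panel class.
CLASS_RULES: Dict[str, Optional[frozenset]] = {
    "CATALYTIC": None,            # identity with the reference residue
    "STABILIZER": None,
    "CYSTEINE": None,
    "ORIENTATION": None,
    "AROMATIC_BINDING": frozenset("FYW"),
    "POLAR_INTERACTOR": frozenset("STNQDEHKR"),
    "ACIDIC_PATCH": frozenset("DE"),
    "HYDROPHOBIC_BUNDLE": frozenset("AVLIMFWC"),
}


@dataclass(frozen=True)
class PanelEntry:
    ref_pos: int
    ref_aa: str
    cls: str


@dataclass
class ResiduePanel:
    reference_id: str
    reference_seq: str
    entries: List[PanelEntry]

    def __post_init__(self) -> None:
        for e in self.entries:
            if self.reference_seq[e.ref_pos - 1] != e.ref_aa:
                raise ValueError(
                    f"panel entry {e.ref_aa}{e.ref_pos} does not match the "
                    f"reference residue {self.reference_seq[e.ref_pos - 1]}")
            if e.cls not in CLASS_RULES:
                raise ValueError(f"unknown residue class {e.cls!r}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def classes(self) -> List[str]:
        return sorted({e.cls for e in self.entries})


@dataclass
class PositionRecord:
    ref_pos: int
    ref_aa: str
    cls: str
    aligned_aa: str  # '-' for a gap
    conserved: bool
    identical: bool


@dataclass
class ConservationProfile:
    id: str
    positions: List[PositionRecord] = field(default_factory=list)

    @property
    def conserved_count(self) -> int:
        return sum(p.conserved for p in self.positions)

    @property
    def identical_count(self) -> int:
        return sum(p.identical for p in self.positions)

    def class_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for p in self.positions:
            counts[p.cls] = counts.get(p.cls, 0) + int(p.conserved)
        return counts


def make_aligner(open_gap: float = 10.0, extend_gap: float = 0.5,
                 matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def align_to_reference(
    query: str,
    reference: str,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Dict[int, str]:
    """Global alignment mapping: reference position (1-based) -> query residue
    or '-' where the query is gapped."""
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = aligner or make_aligner()
    alignment = aligner.align(reference, query)[0]
    mapping = {pos: GAP for pos in range(1, len(reference) + 1)}
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            mapping[t0 + offset + 1] = query[q0 + offset]
    return mapping


def score_panel(mapping: Dict[int, str], panel: ResiduePanel,
                id: str = "") -> ConservationProfile:
    """Score one member's reference mapping against the panel."""
    profile = ConservationProfile(id=id)
    for e in panel.entries:
        aa = mapping.get(e.ref_pos, GAP)
        identical = aa == e.ref_aa
        allowed = CLASS_RULES[e.cls]
        if aa == GAP:
            conserved = False
        elif allowed is None:
            conserved = identical
        else:
            conserved = aa in allowed
        profile.positions.append(
            PositionRecord(e.ref_pos, e.ref_aa, e.cls, aa, conserved, identical))
    return profile


def profile_members(
    seqs: Dict[str, str],
    panel: ResiduePanel,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> List[ConservationProfile]:
    aligner = aligner or make_aligner()
    return [
        score_panel(align_to_reference(seq, panel.reference_seq, aligner),
                    panel, id=name)
        for name, seq in seqs.items()
    ]


def residue_distribution(
    profiles: Sequence[ConservationProfile], ref_pos: int
) -> List[Tuple[str, int]]:
    """Counts of aligned residues at one reference position, descending.

    Gaps are tallied under '-'.  Counts sum to the number of profiles.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    counter: Counter = Counter()
    for prof in profiles:
        for p in prof.positions:
            if p.ref_pos == ref_pos:
                counter[p.aligned_aa] += 1
                break
        else:
            raise ValueError(f"profile {prof.id} lacks position {ref_pos}")
    return counter.most_common()


def _load_packaged_panel(panel_file: str, ref_file: str) -> ResiduePanel:
    base = resources.files("pmekit") / "data"
    seqs = pio.read_fasta(str(base / ref_file))
    ((ref_id, ref_seq),) = seqs.items()
    df = pio.read_panel(str(base / panel_file))
    entries = [PanelEntry(int(row["ref_pos"]), str(row["ref_aa"]), str(row["class"]))
               for _, row in df.iterrows()]
    return ResiduePanel(ref_id, ref_seq, entries)


def default_pme_panel() -> ResiduePanel:
    """The 11-residue PME panel: 3 catalytic, 2 stabilizers, 6 aromatic
    substrate-binding positions."""
    return _load_packaged_panel("pme_panel.tsv", "pme_reference.synthetic.fasta")


def default_pmei_panel() -> ResiduePanel:
    """The PMEI panel: 4 disulfide cysteines, 5 polar PME-interface residues,
    4 acidic-patch positions, 12 hydrophobic-bundle positions and the
    N-terminal orientation position."""
    return _load_packaged_panel("pmei_panel.tsv", "pmei_reference.synthetic.fasta")


def load_panel(panel_path, reference_fasta) -> ResiduePanel:
    seqs = pio.read_fasta(reference_fasta)
    ((ref_id, ref_seq),) = seqs.items()
    df = pio.read_panel(panel_path)
    entries = [PanelEntry(int(row["ref_pos"]), str(row["ref_aa"]), str(row["class"]))
               for _, row in df.iterrows()]
    return ResiduePanel(ref_id, ref_seq, entries)
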