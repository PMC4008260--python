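"""Mature-protein derivation and physicochemical properties (MW, pI).

Secreted PMEs and PMEIs lose their N-terminal targeting/processing segments:
Type-1 PMEs lose the whole pro-region at a tetrapeptide recognition site, and
proteins with a predicted signal peptide lose the signal peptide.  Molecular
weight uses average residue masses; the isoelectric point is the root of the
Henderson-Hasselbalch net-charge function, found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

from .motifs import CleavageReport, TETRAPEPTIDE_LEN
from .records import Family, FamilyAssignment, ProteinRecord

# Average (isotope-abundance weighted) residue masses in Da, i.e. the mass each
# residue contributes inside a peptide chain; a free protein adds one water.
AVERAGE_RESIDUE_MASS: Dict[str, float] = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "E": 129.12, "Q": 128.13, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}
WATER_MASS = 18.02
DEFAULT_X_MASS = 110.0

#: Default pKa values for the ionizable groups.  The set is configurable; the
#: defaults are conventional textbook values.
DEFAULT_PKA: Dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
}
_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


def molecular_weight(seq: str, x_mass: float = DEFAULT_X_MASS) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    if not seq:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in seq.upper():
        if aa == "X":
            total += x_mass
        elif aa in AVERAGE_RESIDUE_MASS:
            total += AVERAGE_RESIDUE_MASS[aa]
        else:
            raise ValueError(f"invalid residue {aa!r}")
    return total


def net_charge(seq: str, ph: float, pka: Optional[Dict[str, float]] = None) -> float:
    """Henderson-Hasselbalch net charge of the protein at a given pH."""
    pka = pka or DEFAULT_PKA
    seq = seq.upper()
    counts = {aa: seq.count(aa) for aa in "DECYHKR"}
    counts["Nterm"] = counts["Cterm"] = 1
    charge = 0.0
    for group in _POSITIVE:
        charge += counts[group] / (1.0 + 10.0 ** (ph - pka[group]))
    for group in _NEGATIVE:
        charge -= counts[group] / (1.0 + 10.0 ** (pka[group] - ph))
    return charge


def isoelectric_point(
    seq: str,
    pka: Optional[Dict[str, float]] = None,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq.upper()) - set(AVERAGE_RESIDUE_MASS) - {"X"}
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)}")
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pka)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


@dataclass
class MatureProtein:
    id: str
    mature_seq: str
    removed: str = ""
    mw_da: float = 0.0
    pi: float = 0.0

    @property
    def n_aa(self) -> int:
        return len(self.mature_seq)

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0


def derive_mature(
    record: ProteinRecord,
    assignment: FamilyAssignment,
    cleavage: Optional[CleavageReport] = None,
    site_choice: str = "BM2",
    pka: Optional[Dict[str, float]] = None,
) -> MatureProtein:
    """Strip the N-terminal processing segments and compute size, MW and pI.

    Type-1 PMEs with at least one accepted recognition site are cut after the
    tetrapeptide; with two sites the downstream one (BM2, adjacent to the PME
    domain) is used by default so the whole pro-region is removed
    (``site_choice`` of "BM1" keeps the upstream cut, "none" disables
    pro-region cleavage).  Otherwise a predicted signal peptide, if any, is
    removed.  Pro-region cleavage subsumes signal-peptide removal.
    """
    seq = record.aa_seq
    mature_start = 1  # 1-based first residue retained
    removed = ""

    positioned = []
    if assignment.family is Family.TYPE1_PME and cleavage is not None \
            and site_choice.lower() != "none":
        positioned = sorted(
            (h for h in cleavage.hits if h.start is not None),
            key=lambda h: h.start,
        )
    if positioned:
        chosen = positioned[0] if site_choice.upper() == "BM1" else positioned[-1]
        cut_end = chosen.start + TETRAPEPTIDE_LEN - 1
        if cut_end >= len(seq):
            raise ValueError(
                f"{record.id}: cleavage after position {cut_end} leaves no "
                f"mature protein (length {len(seq)})")
        mature_start = cut_end + 1
        removed = f"pro-region:1-{cut_end}"
    elif record.topology.has_signal_peptide and record.topology.sp_cleavage_pos:
        pos = record.topology.sp_cleavage_pos
        if pos >= len(seq):
            raise ValueError(
                f"{record.id}: signal-peptide cleavage at {pos} beyond sequence")
        mature_start = pos + 1
        removed = f"signal-peptide:1-{pos}"

    mature = seq[mature_start - 1:]
    return MatureProtein(
        id=record.id,
        mature_seq=mature,
        removed=removed,
        mw_da=molecular_weight(mature),
        pi=isoelectric_point(mature, pka),
    )
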