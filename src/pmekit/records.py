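"""Core data model for PME/PMEI family members.

A family member is a predicted protein with an amino-acid sequence, optional
coding sequence, Pfam-style domain hits (PME, PMEI, or other), topology
annotations (signal peptide, transmembrane segments) produced by external
predictors, and a transcription-evidence flag.  Coordinates are 1-based and
inclusive throughout, matching the residue numbering conventions of the
structural literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class DomainLabel(str, Enum):
    PME = "PME"
    PMEI = "PMEI"
    OTHER = "OTHER"


class Family(str, Enum):
    """Family classes: Type-1 PMEs carry a PMEI-like pro-region ahead of the
    catalytic PME domain, Type-2 PMEs have the PME domain only, and PMEIs have
    the inhibitor domain only."""

    TYPE1_PME = "TYPE1_PME"
    TYPE2_PME = "TYPE2_PME"
    PMEI = "PMEI"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class DomainHit:
    label: DomainLabel
    start: int
    end: int
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("domain coordinates are 1-based")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class TopologyAnnotation:
    """Signal-peptide / transmembrane annotations from external predictors.

    ``sp_cleavage_pos`` is the last residue of the signal peptide; the mature
    protein starts at ``sp_cleavage_pos + 1``.
    """

    has_signal_peptide: bool = False
    sp_cleavage_pos: Optional[int] = None
    has_tm: bool = False
    tm_segments: tuple = ()

    def __post_init__(self) -> None:
        if self.sp_cleavage_pos is not None and not self.has_signal_peptide:
            raise ValueError("sp_cleavage_pos given without a signal peptide")
        if self.has_signal_peptide and self.sp_cleavage_pos is not None:
            if self.sp_cleavage_pos < 1:
                raise ValueError("sp_cleavage_pos is 1-based")


@dataclass(frozen=True)
class ExpressionEvidence:
    """Any experimental support for transcription (qRT-PCR, EST, RNA-seq)."""

    sources: frozenset = frozenset()

    VALID = frozenset({"QPCR", "EST", "RNASEQ"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", frozenset(self.sources))
        unknown = self.sources - self.VALID
        if unknown:
            raise ValueError(f"unknown evidence sources: {sorted(unknown)}")

    @property
    def expressed(self) -> bool:
        return bool(self.sources)


@dataclass(frozen=True)
class FamilyAssignment:
    id: str
    family: Family


@dataclass
class ProteinRecord:
    id: str
    aa_seq: str
    cds_seq: Optional[str] = None
    domains: list = field(default_factory=list)
    topology: TopologyAnnotation = field(default_factory=TopologyAnnotation)
    evidence: ExpressionEvidence = field(default_factory=ExpressionEvidence)

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"{self.id}: empty amino-acid sequence")
        self.aa_seq = self.aa_seq.upper()
        bad = set(self.aa_seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")
        for hit in self.domains:
            if hit.end > len(self.aa_seq):
                raise ValueError(
                    f"{self.id}: domain {hit.label.value} {hit.start}-{hit.end} "
                    f"exceeds sequence length {len(self.aa_seq)}"
                )

    def __len__(self) -> int:
        return len(self.aa_seq)

    def hits(self, label: DomainLabel) -> list:
        return [h for h in self.domains if h.label is label]
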