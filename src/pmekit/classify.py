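"""Domain-based family classification and cross-species family proportions.

Classification is presence/absence logic over resolved domain hits: a protein
with both a PMEI-like and a PME domain is a Type-1 PME (pro-region followed by
the catalytic domain); PME-only proteins are Type-2; PMEI-only proteins are
inhibitors.  Additional unrelated domains never change the class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .records import DomainHit, DomainLabel, Family, FamilyAssignment, ProteinRecord


def classify_family(record: ProteinRecord, evalue_max: float = 1.0) -> FamilyAssignment:
    """Assign a protein to TYPE1_PME / TYPE2_PME / PMEI / UNCLASSIFIED.

    Hits with e-value above ``evalue_max`` are ignored.  Overlapping PME and
    PMEI hits on the same residues are rejected: the two domains are distinct
    structural modules and a shared interval indicates a broken annotation.
    """
    hits = [h for h in record.domains if h.evalue <= evalue_max]
    pme = [h for h in hits if h.label is DomainLabel.PME]
    pmei = [h for h in hits if h.label is DomainLabel.PMEI]
    for a in pme:
        for b in pmei:
            if a.overlaps(b):
                raise ValueError(
                    f"{record.id}: PME hit {a.start}-{a.end} overlaps PMEI hit "
                    f"{b.start}-{b.end}"
                )
    if pme and pmei:
        family = Family.TYPE1_PME
    elif pme:
        family = Family.TYPE2_PME
    elif pmei:
        family = Family.PMEI
    else:
        family = Family.UNCLASSIFIED
    return FamilyAssignment(record.id, family)


def classify_all(records: Iterable[ProteinRecord], evalue_max: float = 1.0):
    return [classify_family(r, evalue_max) for r in records]


@dataclass(frozen=True)
class FamilyProportion:
    """Family size relative to the predicted proteome of one species."""

    species: str
    n_family: int
    n_proteome: int

    @property
    def proportion(self) -> float:
        return self.n_family / self.n_proteome


@dataclass(frozen=True)
class TwoSampleTResult:
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float


def family_proportions(
    tables: Sequence[FamilyProportion],
    group_a: Iterable[str],
    group_b: Iterable[str],
    welch: bool = False,
) -> TwoSampleTResult:
    """Two-sample t-test comparing family proportions between species groups.

    Student's pooled-variance test by default, Welch on request.  Degenerate
    input with zero variance and zero mean difference (e.g. identical vectors
    in both groups) is reported as t=0, p=1.
    """
    by_species = {t.species: t.proportion for t in tables}
    a = np.array([by_species[s] for s in group_a], dtype=float)
    b = np.array([by_species[s] for s in group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 species (variance undefined)")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = len(a) + len(b) - 2
        return TwoSampleTResult(a.mean(), b.mean(), 0.0, df, 1.0)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TwoSampleTResult(a.mean(), b.mean(), float(res.statistic),
                            float(res.df), float(res.pvalue))
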