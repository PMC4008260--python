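"""Fisher's exact test and the conservation-vs-expression comparison.

The central biological question: do genes with experimental evidence of
transcription retain the functionally critical residues more often than genes
with no such evidence?  Panel positions are pooled across genes into a single
2x2 table (conserved / not x expressed / not), which treats positions as
independent — an approximation, but the one implied by pooled family-level
percentages.  A per-residue mode tests each panel position separately, with
no multiple-testing correction by default (Bonferroni / Benjamini-Hochberg
available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple
import warnings

import numpy as np
from scipy import stats as sps

from .conservation import ConservationProfile


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows conserved / not, columns expressed / not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p by the minimum-likelihood method: the sum of
    hypergeometric probabilities of every table with the same margins whose
    probability does not exceed the observed table's."""
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("empty margin: the test is undefined")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def _safe_fisher(table: ContingencyTable2x2) -> Tuple[float, float]:
    """Fisher p and odds ratio, treating a degenerate margin as p = 1: a
    table with an empty row or column margin is the only table with those
    margins, so the enumeration is trivial (e.g. both groups fully
    conserved)."""
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0, float("nan")
    return fisher_exact(table), odds_ratio(table)


def odds_ratio(table: ContingencyTable2x2) -> float:
    if table.b == 0 or table.c == 0:
        return float("inf") if table.a * table.d > 0 else float("nan")
    return (table.a * table.d) / (table.b * table.c)


@dataclass
class GroupFraction:
    n_genes: int
    conserved: int
    total: int

    @property
    def fraction(self) -> float:
        return self.conserved / self.total if self.total else float("nan")


@dataclass
class ConservationExpressionResult:
    expressed: GroupFraction
    non_expressed: GroupFraction
    table: Optional[ContingencyTable2x2] = None
    p: Optional[float] = None
    odds_ratio: Optional[float] = None
    per_residue: Optional[List[dict]] = None


def _correct(pvals: List[float], method: Optional[str]) -> List[float]:
    if method is None:
        return pvals
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if method == "bonferroni":
        return list(np.minimum(p * m, 1.0))
    if method == "bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return list(out)
    raise ValueError(f"unknown correction {method!r}")


def conservation_vs_expression(
    profiles: Sequence[ConservationProfile],
    expressed: Mapping[str, bool],
    mode: str = "aggregate",
    correction: Optional[str] = None,
) -> ConservationExpressionResult:
    """Compare residue conservation between expressed and non-expressed genes.

    ``expressed`` maps every profiled gene id to its evidence flag.  In
    aggregate mode all panel positions are pooled into one 2x2 test; in
    per-residue mode each reference position gets its own table and p-value.
    If one group is empty the fractions are still reported and the test is
    skipped with a warning.
    """
    missing = [p.id for p in profiles if p.id not in expressed]
    if missing:
        raise ValueError(f"no evidence flag for: {missing[:5]}")
    groups = {True: [], False: []}
    for prof in profiles:
        groups[bool(expressed[prof.id])].append(prof)

    def pool(profs: Sequence[ConservationProfile]) -> GroupFraction:
        conserved = sum(p.conserved_count for p in profs)
        total = sum(len(p.positions) for p in profs)
        return GroupFraction(len(profs), conserved, total)

    res = ConservationExpressionResult(pool(groups[True]), pool(groups[False]))
    if not groups[True] or not groups[False]:
        warnings.warn("one evidence group is empty; Fisher test skipped")
        return res

    if mode == "aggregate":
        e, n = res.expressed, res.non_expressed
        res.table = ContingencyTable2x2(e.conserved, e.total - e.conserved,
                                        n.conserved, n.total - n.conserved)
        res.p, res.odds_ratio = _safe_fisher(res.table)
    elif mode == "per_residue":
        rows, pvals = [], []
        positions = [p.ref_pos for p in profiles[0].positions]
        for pos in positions:
            def count(profs, want):
                return sum(
                    1 for pr in profs
                    for rec in pr.positions
                    if rec.ref_pos == pos and rec.conserved == want
                )
            tab = ContingencyTable2x2(
                count(groups[True], True), count(groups[False], True),
                count(groups[True], False), count(groups[False], False))
            # rows here are expressed/non-expressed x conserved/not; Fisher's
            # p is invariant under that transposition
            try:
                p = fisher_exact(tab)
            except ValueError:
                p = float("nan")
            rows.append({"ref_pos": pos, "table": tab, "p": p})
            pvals.append(p)
        for row, p_adj in zip(rows, _correct(pvals, correction)):
            row["p_adj"] = p_adj
        res.per_residue = rows
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return res


def pooled_conservation_test(
    conserved_counts: Mapping[str, int],
    panel_size: int,
    expressed: Mapping[str, bool],
) -> ConservationExpressionResult:
    """Aggregate conservation-vs-expression test from per-gene conserved
    counts (e.g. curated table columns) instead of full profiles."""
    e_cons = sum(c for g, c in conserved_counts.items() if expressed[g])
    n_cons = sum(c for g, c in conserved_counts.items() if not expressed[g])
    n_e = sum(1 for g in conserved_counts if expressed[g])
    n_n = len(conserved_counts) - n_e
    res = ConservationExpressionResult(
        GroupFraction(n_e, e_cons, panel_size * n_e),
        GroupFraction(n_n, n_cons, panel_size * n_n),
    )
    if n_e and n_n:
        e, n = res.expressed, res.non_expressed
        res.table = ContingencyTable2x2(e.conserved, e.total - e.conserved,
                                        n.conserved, n.total - n.conserved)
        res.p, res.odds_ratio = _safe_fisher(res.table)
    else:
        warnings.warn("one evidence group is empty; Fisher test skipped")
    return res
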