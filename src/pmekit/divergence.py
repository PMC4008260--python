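"""Kimura 2-parameter divergence and paralog dating.

For an aligned nucleotide pair the K2P model separates transitions
(A<->G, C<->T; proportion P) from transversions (proportion Q) and corrects
for multiple hits:

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites with a gap or ambiguity code in either sequence are excluded for that
pair only (pairwise deletion).  Divergence times follow the molecular clock
t = K / (2 r) for a substitution rate r per site per year; the default rates
bracket published plant nuclear estimates at 1.5e-8 and 8.1e-9.  Putative
paralog pairs are confirmed by reciprocal best match under a pairwise
alignment score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import Align

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
VALID_BASES = frozenset("ACGT")

#: Substitution rates (per site per year) used for dating, fast and slow.
DEFAULT_RATES: Tuple[float, ...] = (1.5e-8, 8.1e-9)


class SaturationError(ValueError):
    """The observed divergence is too large for the K2P correction."""


@dataclass(frozen=True)
class K2PResult:
    id_pair: Tuple[str, str]
    n_sites_used: int
    P: float
    Q: float
    K: float


@dataclass(frozen=True)
class ParalogPair:
    id_a: str
    id_b: str
    K: float
    times: Mapping[float, float]  # rate -> time in million years


def k2p_distance(seq_a: str, seq_b: str,
                 ids: Tuple[str, str] = ("a", "b")) -> K2PResult:
    """K2P distance between two aligned nucleotide sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a, b = seq_a.upper(), seq_b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in VALID_BASES or y not in VALID_BASES:
            continue  # pairwise deletion of gaps and ambiguity codes
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no retained sites after pairwise deletion")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution saturation: P={P:.3f}, Q={Q:.3f}")
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(ids, n, P, Q, K)


def divergence_time(K: float,
                    rates: Sequence[float] = DEFAULT_RATES) -> Dict[float, float]:
    """Divergence times t = K/(2r) in million years, one per rate."""
    if K < 0:
        raise ValueError("K must be non-negative")
    times = {}
    for r in rates:
        if r <= 0:
            raise ValueError("substitution rates must be positive")
        times[r] = K / (2.0 * r) / 1e6
    return times


def make_paralog_pair(id_a: str, id_b: str, K: float,
                      rates: Sequence[float] = DEFAULT_RATES) -> ParalogPair:
    return ParalogPair(id_a, id_b, K, divergence_time(K, rates))


def _default_scorer(kind: str = "nucleotide") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "protein":
        from Bio.Align import substitution_matrices
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score, aligner.extend_gap_score = -10.0, -0.5
    else:
        aligner.match_score, aligner.mismatch_score = 2.0, -1.0
        aligner.open_gap_score, aligner.extend_gap_score = -5.0, -1.0
    return aligner


@dataclass
class RBHResult:
    pairs: List[Tuple[str, str]] = field(default_factory=list)
    unpaired: List[str] = field(default_factory=list)
    ties: List[str] = field(default_factory=list)


def reciprocal_best_match(
    members: Mapping[str, str],
    score_table: Optional[Mapping[Tuple[str, str], float]] = None,
    kind: str = "nucleotide",
) -> RBHResult:
    """Reciprocal-best-match paralog pairing.

    Scores come from the package's global pairwise aligner or, when supplied,
    from an external score table (symmetric access is handled).  A member
    whose best score is tied between several partners stays unpaired and is
    reported under ``ties``.
    """
    names = list(members)
    if len(names) < 2:
        raise ValueError("need at least 2 members to pair")

    def score(x: str, y: str) -> float:
        if score_table is not None:
            if (x, y) in score_table:
                return float(score_table[(x, y)])
            return float(score_table[(y, x)])
        return float(aligner.score(members[x], members[y]))

    aligner = _default_scorer(kind) if score_table is None else None
    best: Dict[str, Optional[str]] = {}
    tied: Dict[str, bool] = {}
    for x in names:
        scores = {y: score(x, y) for y in names if y != x}
        top = max(scores.values())
        winners = [y for y, s in scores.items() if s == top]
        best[x] = winners[0] if len(winners) == 1 else None
        tied[x] = len(winners) > 1

    result = RBHResult()
    seen = set()
    for x in names:
        y = best[x]
        if y is not None and best.get(y) == x:
            key = tuple(sorted((x, y)))
            if key not in seen:
                seen.add(key)
                result.pairs.append(key)
    paired = {n for p in result.pairs for n in p}
    for x in names:
        if x not in paired:
            result.unpaired.append(x)
            if tied[x]:
                result.ties.append(x)
    return result
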