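"""Proteolytic cleavage-site motif scanning for Type-1 PME pro-regions.

Type-1 PMEs are matured by a subtilisin-like protease that cuts at one of two
alternative tetrapeptide recognition sites (BM1 and BM2) in the linker between
the PMEI-like pro-region and the catalytic PME domain.  The canonical
recognition pattern is ``[RKQ][RKEHLN][LDMI][LMAKR]``.  Genes are classed by
how many recognition sites they carry (two, one, none), with a separate class
for genes whose only site is a divergent ("novel") tetrapeptide occupying the
motif position of related sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

#: Canonical protease-recognition tetrapeptide, one character class per residue.
CANONICAL_PATTERN = "[RKQ][RKEHLN][LDMI][LMAKR]"

#: Divergent tetrapeptides observed at motif-anchored positions in the curated
#: flax dataset.  RRKL and GRLL occur with no accompanying canonical site; the
#: others co-occur with a canonical site in the alternate position.
KNOWN_NOVEL_TETRAPEPTIDES = frozenset(
    {"RRKL", "GRLL", "RKVA", "RRLW", "REYL", "RRFL"}
)

#: Tetrapeptides recorded as accepted cleavage sites in the curated flax
#: dataset although they deviate from the canonical character classes at one
#: position (V in the third position).  The published family counts require
#: these to be treated as matches; ``scan_canonical`` itself never emits them.
CURATED_ACCEPTED_VARIANTS = frozenset({"RKVL", "RRVL"})

TETRAPEPTIDE_LEN = 4


class SiteClass(str, Enum):
    TWO_SITE = "TWO_SITE"
    ONE_SITE = "ONE_SITE"
    NONE = "NONE"
    NOVEL_ONLY = "NOVEL_ONLY"


@dataclass(frozen=True)
class MotifHit:
    """A tetrapeptide occurrence; ``start`` is the 1-based position of its
    first residue (None when the curated source records no position)."""

    start: Optional[int]
    tetrapeptide: str
    canonical: bool


@dataclass
class CleavageReport:
    id: str
    hits: List[MotifHit] = field(default_factory=list)
    novel_hits: List[MotifHit] = field(default_factory=list)
    site_class: SiteClass = SiteClass.NONE
    separation: Optional[int] = None


def is_canonical(tetrapeptide: str, pattern: str = CANONICAL_PATTERN) -> bool:
    return re.fullmatch(pattern, tetrapeptide) is not None


def scan_canonical(
    seq: str,
    region: Optional[Tuple[int, int]] = None,
    pattern: str = CANONICAL_PATTERN,
) -> List[MotifHit]:
    """All (possibly overlapping) canonical tetrapeptide matches, ascending.

    ``region`` restricts the scan to a 1-based inclusive interval — normally
    the pro-region/PME-domain linker.  Hits must lie entirely inside it.
    """
    if region is None:
        lo, hi = 1, len(seq)
    else:
        lo, hi = region
        if lo < 1 or hi > len(seq) or lo > hi:
            raise ValueError(
                f"region {lo}-{hi} outside sequence of length {len(seq)}")
    window = seq[lo - 1:hi]
    rx = re.compile("(?=(" + pattern + "))")
    return [
        MotifHit(lo + m.start(), m.group(1), True)
        for m in rx.finditer(window)
        if m.start() + TETRAPEPTIDE_LEN <= len(window)
    ]


def linker_region(seq_len: int, pmei_end: int, pme_start: int,
                  margin: int = 10) -> Tuple[int, int]:
    """The inter-domain linker, each side extended by ``margin`` residues."""
    lo = max(1, pmei_end - margin + 1)
    hi = min(seq_len, pme_start + margin - 1)
    if lo > hi:
        raise ValueError("PMEI domain ends after the PME domain starts")
    return lo, hi


def separation_between(first: MotifHit, second: MotifHit) -> int:
    """Residues strictly between two tetrapeptides: start2 - start1 - 4."""
    return second.start - first.start - TETRAPEPTIDE_LEN


def _choose_pair(hits: Sequence[MotifHit],
                 window: Tuple[int, int]) -> Tuple[MotifHit, MotifHit]:
    ordered = sorted(hits, key=lambda h: h.start)
    if len(ordered) == 2:
        return ordered[0], ordered[1]
    in_window = [
        (a, b)
        for i, a in enumerate(ordered)
        for b in ordered[i + 1:]
        if window[0] <= separation_between(a, b) <= window[1]
    ]
    if in_window:
        # tie-break toward the most C-terminal pair
        return max(in_window, key=lambda ab: (ab[1].start, ab[0].start))
    return ordered[0], ordered[1]


def classify_sites(
    hits: Sequence[MotifHit],
    novel_hits: Sequence[MotifHit] = (),
    id: str = "",
    pair_window: Tuple[int, int] = (11, 33),
) -> CleavageReport:
    """Class a gene by its recognition-site content.

    TWO_SITE for two or more canonical hits (the separation is reported for
    the pair whose spacing falls in the BM1-BM2 window, preferring the most
    C-terminal such pair); ONE_SITE for exactly one; NOVEL_ONLY when only a
    divergent tetrapeptide occupies the motif position; NONE otherwise.
    """
    hits = list(hits)
    novel_hits = list(novel_hits)
    report = CleavageReport(id=id, hits=hits, novel_hits=novel_hits)
    if len(hits) >= 2:
        report.site_class = SiteClass.TWO_SITE
        if all(h.start is not None for h in hits):
            a, b = _choose_pair(hits, pair_window)
            report.separation = separation_between(a, b)
    elif len(hits) == 1:
        report.site_class = SiteClass.ONE_SITE
    elif novel_hits:
        report.site_class = SiteClass.NOVEL_ONLY
    else:
        report.site_class = SiteClass.NONE
    return report


def report_from_curated(
    gene: str,
    bm1: str,
    bm2: str,
    positions: str,
    novel_set: frozenset = KNOWN_NOVEL_TETRAPEPTIDES,
) -> CleavageReport:
    """Build a cleavage report from curated table fields.

    ``bm1``/``bm2`` are recorded tetrapeptides (empty when absent) and
    ``positions`` the recorded start position(s), dash-joined for two sites.
    Canonicality follows the curation: any recorded motif not in the
    enumerated novel set is an accepted recognition site (this includes the
    single-position variants that deviate from the strict pattern; see
    ``CURATED_ACCEPTED_VARIANTS``).
    """
    motifs = [m for m in (bm1.strip(), bm2.strip()) if m]
    starts: List[Optional[int]] = [
        int(p) for p in positions.replace(" ", "").split("-") if p
    ]
    while len(starts) < len(motifs):
        starts.append(None)
    canonical, novel = [], []
    for motif, start in zip(motifs, starts):
        hit = MotifHit(start, motif, motif not in novel_set)
        (canonical if hit.canonical else novel).append(hit)
    return classify_sites(canonical, novel, id=gene)


def flag_novel(
    msa: Dict[str, str],
    canonical_hits: Dict[str, Sequence[MotifHit]],
    min_fraction: float = 0.5,
) -> Dict[str, List[MotifHit]]:
    """Column-anchored novel-motif calls on an aligned phylogenetic group.

    Alignment columns where at least ``min_fraction`` of the members carry a
    canonical hit define motif-anchored windows; members without a canonical
    hit there report the ungapped tetrapeptide occupying the window.  Members
    gapped anywhere across the window make no call.
    """
    if len(msa) < 2:
        raise ValueError("novel-motif voting needs at least 2 aligned members")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")

    # map each member's unaligned hit starts to alignment columns
    col_of: Dict[str, Dict[int, int]] = {}
    for name, aligned in msa.items():
        mapping, pos = {}, 0
        for col, ch in enumerate(aligned):
            if ch != "-":
                pos += 1
                mapping[pos] = col
        col_of[name] = mapping

    anchors: Dict[int, set] = {}
    for name, hits in canonical_hits.items():
        for hit in hits:
            if hit.start is None:
                continue
            col = col_of[name].get(hit.start)
            if col is not None:
                anchors.setdefault(col, set()).add(name)

    n = len(msa)
    out: Dict[str, List[MotifHit]] = {name: [] for name in msa}
    for col in sorted(anchors):
        supporters = anchors[col]
        if len(supporters) / n < min_fraction:
            continue
        for name, aligned in msa.items():
            if name in supporters:
                continue
            window = aligned[col:col + TETRAPEPTIDE_LEN]
            if len(window) < TETRAPEPTIDE_LEN or "-" in window:
                continue  # gap rule: no call
            ungapped_start = sum(1 for ch in aligned[:col] if ch != "-") + 1
            out[name].append(MotifHit(ungapped_start, window,
                                      is_canonical(window)))
    # only non-canonical windows are novel calls
    return {name: [h for h in hits if not h.canonical]
            for name, hits in out.items()}
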