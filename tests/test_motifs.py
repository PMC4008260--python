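"""Cleavage-motif scanning, site classing, and novel-motif voting."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from pmekit import (MotifHit, SiteClass, classify_sites, flag_novel,
                    is_canonical, linker_region, scan_canonical)
from pmekit.motifs import (CANONICAL_PATTERN, KNOWN_NOVEL_TETRAPEPTIDES,
                           report_from_curated, separation_between)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scan(seq):
    """Oracle: check every 4-mer window against the character classes."""
    classes = ["RKQ", "RKEHLN", "LDMI", "LMAKR"]
    hits = []
    for i in range(len(seq) - 3):
        window = seq[i:i + 4]
        if all(ch in cls for ch, cls in zip(window, classes)):
            hits.append((i + 1, window))
    return hits


def test_canonical_hit_found_at_correct_position():
    hits = scan_canonical("AARKLLGG")
    assert [(h.start, h.tetrapeptide) for h in hits] == [(3, "RKLL")]
    assert hits[0].canonical


def test_first_position_class_excludes_g():
    assert scan_canonical("AAGRLLGG") == []


def test_overlapping_matches_are_all_reported():
    # 'RRLLL' matches at both 1 (RRLL) and 2 (RLLL)
    hits = scan_canonical("RRLLL")
    assert [(h.start, h.tetrapeptide) for h in hits] == brute_force_scan("RRLLL")
    assert len(hits) == 2


@settings(derandomize=True, max_examples=60)
@given(st.text(alphabet=AA, min_size=4, max_size=200))
def test_scan_equals_exhaustive_window_oracle(seq):
    got = [(h.start, h.tetrapeptide) for h in scan_canonical(seq)]
    assert got == brute_force_scan(seq)


def test_region_restricts_and_validates():
    seq = "RKLL" + "G" * 20 + "RKLL" + "G" * 20
    assert len(scan_canonical(seq)) == 2
    assert [h.start for h in scan_canonical(seq, region=(10, 40))] == [25]
    with pytest.raises(ValueError):
        scan_canonical(seq, region=(0, 10))
    with pytest.raises(ValueError):
        scan_canonical(seq, region=(5, 1000))


def test_linker_region_with_margin():
    assert linker_region(600, pmei_end=180, pme_start=220, margin=10) == (171, 229)
    assert linker_region(200, pmei_end=180, pme_start=195, margin=10) == (171, 200)
    with pytest.raises(ValueError):
        linker_region(600, pmei_end=300, pme_start=200, margin=0)


# ---------------------------------------------------------------------------
# site classing


def hit(start, tet="RKLL", canonical=True):
    return MotifHit(start, tet, canonical)


@pytest.mark.parametrize("starts, expected_sep", [
    ((224, 242), 14),
    ((246, 283), 33),
])
def test_two_site_separation_matches_printed_pairs(starts, expected_sep):
    rep = classify_sites([hit(s) for s in starts])
    assert rep.site_class is SiteClass.TWO_SITE
    assert rep.separation == expected_sep


def test_site_class_taxonomy():
    assert classify_sites([hit(10)]).site_class is SiteClass.ONE_SITE
    assert classify_sites([]).site_class is SiteClass.NONE
    novel = [MotifHit(10, "GRLL", False)]
    assert classify_sites([], novel).site_class is SiteClass.NOVEL_ONLY
    # a canonical hit outranks accompanying novel hits
    assert classify_sites([hit(10)], novel).site_class is SiteClass.ONE_SITE


def test_separation_is_translation_invariant():
    for shift in (0, 7, 100):
        rep = classify_sites([hit(224 + shift), hit(242 + shift)])
        assert rep.separation == 14


def test_three_hits_prefer_in_window_most_cterminal_pair():
    # pairs: (10,20)->6, (20,44)->20, (10,44)->30; both 20 and 30 in window,
    # tie-break toward the most C-terminal pair (20,44)
    rep = classify_sites([hit(10), hit(20), hit(44)])
    assert rep.separation == 20


def test_separation_between_definition():
    assert separation_between(hit(224), hit(242)) == 14


# ---------------------------------------------------------------------------
# curated-table classification


def test_curated_two_site_row():
    rep = report_from_curated("g", "RRLL", "RKLL", "224-242")
    assert rep.site_class is SiteClass.TWO_SITE and rep.separation == 14


def test_curated_novel_only_rows():
    for bm2 in ("GRLL", "RRKL"):
        rep = report_from_curated("g", "", bm2, "")
        assert rep.site_class is SiteClass.NOVEL_ONLY


def test_curated_pair_with_novel_member_is_one_site():
    rep = report_from_curated("g", "RKVA", "RRLL", "235-259")
    assert rep.site_class is SiteClass.ONE_SITE


def test_curated_accepted_variant_counts_as_site():
    # recorded in the curation as a match despite the V in position 3
    rep = report_from_curated("g", "", "RKVL", "358")
    assert rep.site_class is SiteClass.ONE_SITE
    assert not is_canonical("RKVL")  # the strict pattern still rejects it


# ---------------------------------------------------------------------------
# novel-motif voting on an alignment


def msa_group():
    # four aligned members; three carry RKLL at columns 5-8
    return {
        "a": "GGGG" + "RKLL" + "GG",
        "b": "GGGG" + "RKLL" + "GG",
        "c": "GGGG" + "RKLL" + "GG",
        "d": "GGGG" + "RRKL" + "GG",
    }


def hits_for(msa):
    return {name: scan_canonical(seq.replace("-", ""))
            for name, seq in msa.items()}


def test_minority_member_reports_novel_tetrapeptide():
    msa = msa_group()
    novel = flag_novel(msa, hits_for(msa))
    assert [h.tetrapeptide for h in novel["d"]] == ["RRKL"]
    assert novel["a"] == novel["b"] == novel["c"] == []


def test_all_canonical_yields_no_novel_calls():
    msa = {k: "GGGG" + "RKLL" + "GG" for k in "abc"}
    novel = flag_novel(msa, hits_for(msa))
    assert all(v == [] for v in novel.values())


def test_gapped_member_makes_no_call():
    msa = msa_group()
    msa["d"] = "GGGG" + "R-KL" + "GG"  # gap inside the motif window
    novel = flag_novel(msa, hits_for(msa))
    assert novel["d"] == []


def test_below_threshold_window_is_ignored():
    msa = {
        "a": "GGGGRKLLGG",
        "b": "GGGGAAAAGG",
        "c": "GGGGAAAAGG",
        "d": "GGGGAAAAGG",
    }
    novel = flag_novel(msa, hits_for(msa), min_fraction=0.5)
    assert all(v == [] for v in novel.values())


def test_novel_set_matches_strict_pattern_complement():
    for tet in KNOWN_NOVEL_TETRAPEPTIDES:
        assert not is_canonical(tet)
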