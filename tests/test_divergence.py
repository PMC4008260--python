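"""K2P distances, divergence dating, and reciprocal-best-match pairing."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from pmekit import (SaturationError, divergence_time, k2p_distance,
                    make_paralog_pair, reciprocal_best_match)
from pmekit.synthetic import evolve_pair, simulate_paralog_pairs

PUR, PYR = set("AG"), set("CT")


def counting_oracle(a, b):
    """Site-by-site oracle with explicit pairwise deletion."""
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if (x in PUR and y in PUR) or (x in PYR and y in PYR):
                ts += 1
            else:
                tv += 1
    P, Q = ts / n, tv / n
    return n, P, Q, -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def test_identical_sequences_have_zero_distance():
    res = k2p_distance("ACGTACGT", "ACGTACGT")
    assert res.P == res.Q == 0.0 and res.K == 0.0
    assert res.n_sites_used == 8


def test_closed_form_ten_transitions_in_hundred():
    a = "A" * 100
    b = "G" * 10 + "A" * 90
    res = k2p_distance(a, b)
    assert res.P == pytest.approx(0.10) and res.Q == 0.0
    assert res.K == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)


def test_matches_counting_oracle_with_injected_gaps(rng):
    for _ in range(10):
        a, b = evolve_pair(300, float(rng.uniform(0.02, 0.4)), 2.0, rng=rng)
        a = list(a)
        b = list(b)
        for i in rng.integers(0, 300, size=15):
            a[i] = "-"
        for i in rng.integers(0, 300, size=15):
            b[i] = "N"
        a, b = "".join(a), "".join(b)
        res = k2p_distance(a, b)
        n, P, Q, K = counting_oracle(a, b)
        assert (res.n_sites_used, res.P, res.Q) == (n, P, Q)
        assert res.K == pytest.approx(K, abs=1e-12)


def test_agrees_with_r_ape_library():
    """Independent cross-check against ape's K80 distance (pairwise deletion)."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the ape oracle")
    a, b = evolve_pair(600, 0.2, 2.0, seed=42)
    a = a[:50] + "-" * 10 + a[60:]
    import tempfile, os
    with tempfile.TemporaryDirectory() as tmp:
        fasta = os.path.join(tmp, "pair.fasta")
        with open(fasta, "w") as fh:
            fh.write(f">a\n{a}\n>b\n{b}\n")
        script = os.path.join(tmp, "k2p.R")
        with open(script, "w") as fh:
            fh.write(
                'suppressMessages(library(ape))\n'
                f'seqs <- read.dna("{fasta}", format="fasta")\n'
                'd <- dist.dna(seqs, model="K80", pairwise.deletion=TRUE)\n'
                'cat(sprintf("%.10f", as.numeric(d)))\n')
        out = subprocess.run(["Rscript", script], capture_output=True,
                             text=True, check=True)
    assert k2p_distance(a, b).K == pytest.approx(float(out.stdout), abs=1e-9)


def test_symmetry_and_shared_gap_column_invariance():
    a, b = evolve_pair(400, 0.15, 2.0, seed=9)
    assert k2p_distance(a, b).K == k2p_distance(b, a).K
    a2, b2 = a[:100] + "-" + a[100:], b[:100] + "-" + b[100:]
    assert k2p_distance(a2, b2).K == pytest.approx(k2p_distance(a, b).K)


def test_correction_inflates_distance(rng):
    for _ in range(10):
        a, b = evolve_pair(500, float(rng.uniform(0.05, 0.5)), 2.0, rng=rng)
        res = k2p_distance(a, b)
        assert res.K >= res.P + res.Q - 1e-12


def test_saturation_and_empty_site_errors():
    with pytest.raises(SaturationError):
        k2p_distance("A" * 100, "G" * 100)
    with pytest.raises(ValueError):
        k2p_distance("---", "AC-")
    with pytest.raises(ValueError):
        k2p_distance("ACGT", "ACG")


# ---------------------------------------------------------------------------
# dating


def test_divergence_time_arithmetic():
    times = divergence_time(0.3, [1.5e-8])
    assert times[1.5e-8] == pytest.approx(10.0)


def test_rate_ratio_identity():
    for K in (0.01, 0.135, 0.5):
        t = divergence_time(K)
        assert t[8.1e-9] / t[1.5e-8] == pytest.approx(1.5 / 0.81, rel=1e-12)


def test_paralog_pair_times_scale_linearly():
    p1 = make_paralog_pair("a", "b", 0.1)
    p2 = make_paralog_pair("a", "b", 0.2)
    for r in p1.times:
        assert p2.times[r] == pytest.approx(2 * p1.times[r])


def test_k2p_estimator_recovers_true_distance():
    """Mean estimated K over replicates stays within 3 s.e. of truth."""
    for K_true in (0.05, 0.135, 0.2):
        est = []
        rng = np.random.default_rng(int(K_true * 1000))
        for _ in range(200):
            a, b = evolve_pair(1000, K_true, 2.0, rng=rng)
            est.append(k2p_distance(a, b).K)
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - K_true) < 3 * se


def test_higher_ts_tv_ratio_raises_p_over_q():
    ratios = []
    for R in (0.5, 2.0, 8.0):
        rng = np.random.default_rng(17)
        ps, qs = [], []
        for _ in range(30):
            a, b = evolve_pair(1000, 0.2, R, rng=rng)
            res = k2p_distance(a, b)
            ps.append(res.P)
            qs.append(res.Q)
        ratios.append(np.mean(ps) / np.mean(qs))
    assert ratios[0] < ratios[1] < ratios[2]


# ---------------------------------------------------------------------------
# reciprocal best match


def test_two_members_always_pair():
    a, b = evolve_pair(300, 0.1, 2.0, seed=1)
    res = reciprocal_best_match({"a": a, "b": b})
    assert res.pairs == [("a", "b")] and res.unpaired == []


def test_planted_pairs_all_recovered():
    seqs, pairs = simulate_paralog_pairs(10, length=500, K_true=0.1, seed=4)
    res = reciprocal_best_match(seqs)
    assert sorted(res.pairs) == sorted(pairs)


def test_identical_triplet_left_unpaired_with_tie_diagnostic():
    s = "ACGT" * 50
    res = reciprocal_best_match({"x": s, "y": s, "z": s})
    assert res.pairs == []
    assert sorted(res.unpaired) == ["x", "y", "z"]
    assert sorted(res.ties) == ["x", "y", "z"]


def test_score_table_input_is_supported():
    table = {("a", "b"): 10.0, ("a", "c"): 5.0, ("b", "c"): 4.0}
    res = reciprocal_best_match({"a": "", "b": "", "c": ""},
                                score_table=table)
    assert res.pairs == [("a", "b")] and res.unpaired == ["c"]
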