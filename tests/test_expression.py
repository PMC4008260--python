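"""Delta-CT normalization, detection calls, and tissue set algebra."""

import numpy as np
import pandas as pd
import pytest

from pmekit import TissuePanel, delta_ct, detect, detection_matrix, tissue_sets
from pmekit.expression import venn_counts
from pmekit.synthetic import CtSimSpec, simulate_ct


def wells_from(rows):
    return pd.DataFrame(rows, columns=["gene", "tissue", "biorep", "techrep",
                                       "ct", "quality"])


def simple_wells(gene_ct=25.0, ctrl_cts=(20.0, 20.0, 20.0), quality=0.9):
    rows = []
    for br in (1, 2, 3):
        rows.append(("g1", "SA", br, 1, gene_ct, quality))
        for i, ct in enumerate(ctrl_cts):
            rows.append((f"c{i+1}", "SA", br, 1, ct, quality))
    return wells_from(rows)


def test_delta_ct_against_equal_controls():
    out = delta_ct(simple_wells(), controls=["c1", "c2", "c3"])
    row = out[out["gene"] == "g1"].iloc[0]
    assert row["delta_ct_mean"] == pytest.approx(5.0)
    assert row["n_bioreps_valid"] == 3 and row["detected"]


def test_geometric_mean_reference():
    out = delta_ct(simple_wells(ctrl_cts=(19.0, 20.0, 21.0)),
                   controls=["c1", "c2", "c3"])
    ref = (19.0 * 20.0 * 21.0) ** (1 / 3)
    row = out[out["gene"] == "g1"].iloc[0]
    assert ref == pytest.approx(19.9833, abs=1e-4)
    assert row["delta_ct_mean"] == pytest.approx(25.0 - ref, abs=1e-6)


def test_constant_ct_shift_cancels():
    # exact cancellation holds when the controls agree within a biorep (the
    # geometric mean is then the common value, which shifts with the data)
    base = simple_wells(ctrl_cts=(20.5, 20.5, 20.5))
    shifted = base.copy()
    shifted["ct"] = shifted["ct"] + 3.7
    a = delta_ct(base, controls=["c1", "c2", "c3"])
    b = delta_ct(shifted, controls=["c1", "c2", "c3"])
    assert a[a.gene == "g1"]["delta_ct_mean"].iloc[0] == pytest.approx(
        b[b.gene == "g1"]["delta_ct_mean"].iloc[0])


def test_control_gene_against_equal_controls_has_zero_delta():
    out = delta_ct(simple_wells(), controls=["c1", "c2", "c3"])
    for c in ("c1", "c2", "c3"):
        assert out[out.gene == c]["delta_ct_mean"].iloc[0] == pytest.approx(0.0)


def test_low_quality_wells_are_dropped():
    rows = []
    for br in (1, 2, 3):
        rows.append(("g1", "SA", br, 1, 25.0, 0.64))   # below threshold
        rows.append(("c1", "SA", br, 1, 20.0, 0.9))
    out = delta_ct(wells_from(rows), controls=["c1"])
    row = out[out.gene == "g1"].iloc[0]
    assert row["n_bioreps_valid"] == 0 and not row["detected"]


def test_invalid_control_biorep_invalidates_gene_biorep():
    rows = []
    for br in (1, 2, 3):
        rows.append(("g1", "SA", br, 1, 25.0, 0.9))
        rows.append(("c1", "SA", br, 1, 20.0, 0.9 if br < 3 else 0.3))
    out = delta_ct(wells_from(rows), controls=["c1"])
    row = out[out.gene == "g1"].iloc[0]
    assert row["n_bioreps_valid"] == 2 and row["detected"]


def test_se_defined_only_with_two_or_more_bioreps():
    rows = [("g1", "SA", 1, 1, 25.0, 0.9), ("c1", "SA", 1, 1, 20.0, 0.9),
            ("g1", "L", 1, 1, 25.0, 0.9), ("g1", "L", 2, 1, 26.0, 0.9),
            ("c1", "L", 1, 1, 20.0, 0.9), ("c1", "L", 2, 1, 20.0, 0.9)]
    out = delta_ct(wells_from(rows), controls=["c1"])
    one = out[(out.gene == "g1") & (out.tissue == "SA")].iloc[0]
    two = out[(out.gene == "g1") & (out.tissue == "L")].iloc[0]
    assert np.isnan(one["delta_ct_se"]) and not one["detected"]
    # delta-CT values 5.0 and 6.0: sd = 1/sqrt(2), se = sd/sqrt(2) = 0.5
    assert two["delta_ct_se"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# detection


def test_detection_requires_quality_and_min_bioreps():
    rows = [("g1", "SA", br, tr, 25.0, q)
            for br, tr, q in [(1, 1, 0.64), (2, 1, 0.64), (3, 1, 0.64)]]
    assert not detect(wells_from(rows)).detected.any()
    rows = [("g1", "SA", 1, 1, 25.0, 0.65), ("g1", "SA", 2, 1, 25.0, 0.9)]
    assert detect(wells_from(rows)).detected.all()
    rows = [("g1", "SA", 1, 1, 25.0, 0.9)]
    assert not detect(wells_from(rows)).detected.any()


def test_lower_quality_threshold_is_monotone():
    spec = CtSimSpec(seed=3, low_quality_rate=0.3, dropout_rate=0.1)
    wells = simulate_ct(spec).wells
    strict = detect(wells, quality_min=0.65).detected.sum()
    loose = detect(wells, quality_min=0.30).detected.sum()
    assert loose >= strict


# ---------------------------------------------------------------------------
# tissue sets


def calls_from_truth(membership):
    rows = []
    for gene, tissues in membership.items():
        for t in ("EF", "LF", "ECP", "LCP", "SA"):
            rows.append({"gene": gene, "tissue": t,
                         "n_bioreps_valid": 3 if t in tissues else 0,
                         "detected": t in tissues})
    return pd.DataFrame(rows)


def test_venn_counts_match_planted_membership():
    membership = {
        "g1": {"EF"}, "g2": {"LF"}, "g3": {"EF", "LF"},
        "g4": {"EF"}, "g5": set(), "g6": {"SA"},
    }
    calls = calls_from_truth(membership)
    summary = tissue_sets(calls, {"fibers": {"EF": ["EF"], "LF": ["LF"]}})
    counts = venn_counts(summary, "fibers")
    assert counts[frozenset({"EF"})] == 2
    assert counts[frozenset({"LF"})] == 1
    assert counts[frozenset({"EF", "LF"})] == 1
    assert sum(counts.values()) == 4  # genes detected in >=1 grouped tissue


def test_tissue_specific_and_percentages():
    membership = {"g1": {"SA"}, "g2": {"SA", "EF"}, "g3": {"LF"}}
    summary = tissue_sets(calls_from_truth(membership), {})
    assert summary.tissue_specific["SA"] == ["g1"]
    assert summary.n_detected_anywhere == 3
    assert summary.per_tissue_pct["SA"] == pytest.approx(100 * 2 / 3)


def test_all_genes_everywhere_only_full_intersection():
    membership = {f"g{i}": {"EF", "LF"} for i in range(4)}
    summary = tissue_sets(calls_from_truth(membership),
                          {"fibers": {"EF": ["EF"], "LF": ["LF"]}})
    counts = venn_counts(summary, "fibers")
    assert counts == {frozenset({"EF", "LF"}): 4}


def test_unknown_tissue_label_rejected():
    calls = pd.DataFrame([{"gene": "g", "tissue": "NOPE",
                           "n_bioreps_valid": 3, "detected": True}])
    with pytest.raises(ValueError, match="NOPE"):
        tissue_sets(calls, {})


def test_duplicate_panel_labels_rejected():
    with pytest.raises(ValueError):
        TissuePanel(("SA", "SA"))


# ---------------------------------------------------------------------------
# recovery on simulated matrices


def test_planted_fourfold_difference_recovers_ddct_of_two():
    abundance = {("g1", "SA"): 4.0, ("g1", "L"): 2.0}
    reps = []
    for seed in range(12):
        spec = CtSimSpec(genes=("g1",), tissues=("SA", "L"), seed=seed,
                         abundance=abundance, noise_sd=0.25,
                         dropout_rate=0.0, low_quality_rate=0.0)
        out = delta_ct(simulate_ct(spec).wells, controls=list(spec.controls))
        sa = out[(out.gene == "g1") & (out.tissue == "SA")].delta_ct_mean.iloc[0]
        le = out[(out.gene == "g1") & (out.tissue == "L")].delta_ct_mean.iloc[0]
        reps.append(le - sa)
    se = np.std(reps, ddof=1) / np.sqrt(len(reps))
    assert abs(np.mean(reps) - 2.0) < 3 * se + 0.05
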