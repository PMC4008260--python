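"""Delta-CT expression profiling of microfluidic qRT-PCR arrays.

Wells (gene x tissue x biological replicate x technical replicate) are
filtered on the platform quality score, technical replicates are averaged,
and each gene's CT is normalized against the geometric mean of the endogenous
control genes measured in the same tissue/biological replicate:

    dCT = CT_gene - geometric_mean(CT_controls)

Larger dCT therefore means *less* abundant transcript; an inverted sign
convention (an abundance score) is available.  A gene counts as detected in a
tissue when at least ``min_bioreps`` biological replicates contain at least
one quality-passing well.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The twelve assayed tissues, in display order: shoot apex, leaves, roots,
#: early cortical peel, early fibers, senescent leaves, xylem, late cortical
#: peel, late fibers, flower buds, flowers, green bolls.
DEFAULT_TISSUES = ("SA", "L", "R", "ECP", "EF", "SL", "X", "LCP", "LF", "FB", "F", "B")

DEFAULT_QUALITY_MIN = 0.65
DEFAULT_MIN_BIOREPS = 2


@dataclass(frozen=True)
class TissuePanel:
    tissues: Tuple[str, ...] = DEFAULT_TISSUES

    def __post_init__(self) -> None:
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")

    def validate(self, labels: Iterable[str]) -> None:
        unknown = sorted(set(labels) - set(self.tissues))
        if unknown:
            raise ValueError(f"unknown tissue labels: {unknown}")


def _passing(wells: pd.DataFrame, quality_min: float) -> pd.DataFrame:
    return wells[(wells["quality"] >= quality_min) & wells["ct"].notna()]


def delta_ct(
    wells: pd.DataFrame,
    controls: Sequence[str],
    quality_min: float = DEFAULT_QUALITY_MIN,
    min_bioreps: int = DEFAULT_MIN_BIOREPS,
    invert_sign: bool = False,
) -> pd.DataFrame:
    """Per gene x tissue dCT summary over biological replicates.

    Returns a long-format frame with columns ``gene, tissue, delta_ct_mean,
    delta_ct_se, n_bioreps_valid, detected``.  Technical replicates failing
    the quality threshold are dropped before averaging; a biological
    replicate with no valid control wells is invalid for every gene in that
    tissue (logged as a warning).  The standard error is the sample standard
    deviation over valid biological replicates divided by sqrt(n) and is
    reported only when n >= 2.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("at least one endogenous control gene is required")
    ok = _passing(wells, quality_min)
    # mean CT over passing technical replicates, per gene/tissue/biorep
    per_rep = (ok.groupby(["gene", "tissue", "biorep"], as_index=False)["ct"]
                 .mean())

    ctrl = per_rep[per_rep["gene"].isin(controls)]
    # geometric mean of the control CT values per tissue/biorep
    ref = (ctrl.groupby(["tissue", "biorep"])["ct"]
               .apply(lambda v: float(np.exp(np.log(v).mean())))
               .rename("ref_ct").reset_index())

    all_reps = wells[["tissue", "biorep"]].drop_duplicates()
    missing = all_reps.merge(ref, on=["tissue", "biorep"], how="left")
    for row in missing[missing["ref_ct"].isna()].itertuples(index=False):
        logger.warning(
            "no valid control wells in tissue %s / biorep %s; "
            "replicate dropped for all genes", row.tissue, row.biorep)

    merged = per_rep.merge(ref, on=["tissue", "biorep"], how="inner")
    merged["delta_ct"] = merged["ct"] - merged["ref_ct"]
    if invert_sign:
        merged["delta_ct"] = -merged["delta_ct"]

    def summarize(group: pd.DataFrame) -> pd.Series:
        vals = group["delta_ct"].to_numpy()
        n = len(vals)
        return pd.Series({
            "delta_ct_mean": float(np.mean(vals)),
            "delta_ct_se": float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan,
            "n_bioreps_valid": n,
        })

    out = (merged.groupby(["gene", "tissue"])
                 .apply(summarize, include_groups=False)
                 .reset_index())
    out["n_bioreps_valid"] = out["n_bioreps_valid"].astype(int)
    out["detected"] = out["n_bioreps_valid"] >= min_bioreps

    # genes/tissues with no valid replicate at all still get a row
    frame = wells[["gene", "tissue"]].drop_duplicates()
    out = frame.merge(out, on=["gene", "tissue"], how="left")
    out["n_bioreps_valid"] = out["n_bioreps_valid"].fillna(0).astype(int)
    out["detected"] = out["detected"].notna() & out["detected"].eq(True)
    return out


def detect(
    wells: pd.DataFrame,
    quality_min: float = DEFAULT_QUALITY_MIN,
    min_bioreps: int = DEFAULT_MIN_BIOREPS,
) -> pd.DataFrame:
    """Detection calls per gene x tissue from raw wells.

    A gene is detected in a tissue when at least ``min_bioreps`` biological
    replicates have at least one well passing the quality threshold.
    """
    ok = _passing(wells, quality_min)
    n_reps = (ok.groupby(["gene", "tissue"])["biorep"].nunique()
                .rename("n_bioreps_valid").reset_index())
    frame = wells[["gene", "tissue"]].drop_duplicates()
    out = frame.merge(n_reps, on=["gene", "tissue"], how="left")
    out["n_bioreps_valid"] = out["n_bioreps_valid"].fillna(0).astype(int)
    out["detected"] = out["n_bioreps_valid"] >= min_bioreps
    return out


def detection_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot detection calls to a gene x tissue boolean matrix."""
    return (calls.pivot(index="gene", columns="tissue", values="detected")
                 .fillna(False).astype(bool))


@dataclass
class TissueSetSummary:
    venn: Dict[str, Dict[frozenset, List[str]]] = field(default_factory=dict)
    per_tissue_pct: Dict[str, float] = field(default_factory=dict)
    tissue_specific: Dict[str, List[str]] = field(default_factory=dict)
    n_detected_anywhere: int = 0


def tissue_sets(
    calls: pd.DataFrame,
    groupings: Mapping[str, Mapping[str, Sequence[str]]],
    panel: Optional[TissuePanel] = None,
) -> TissueSetSummary:
    """Set-algebra summaries of detection calls.

    ``groupings`` maps a grouping name to ``{group label: tissue list}``; for
    each grouping the genes detected in every exclusive Venn region are
    listed.  Per-tissue detection percentages use the genes detected in at
    least one tissue as the denominator, and genes detected in exactly one
    tissue are listed as tissue-specific.
    """
    panel = panel or TissuePanel()
    panel.validate(calls["tissue"].unique())
    mat = detection_matrix(calls)
    detected_any = mat.any(axis=1)
    genes_any = list(mat.index[detected_any])
    summary = TissueSetSummary(n_detected_anywhere=len(genes_any))

    for tissue in mat.columns:
        summary.per_tissue_pct[tissue] = (
            100.0 * mat.loc[genes_any, tissue].sum() / len(genes_any)
            if genes_any else 0.0
        )

    for gene in genes_any:
        hits = mat.columns[mat.loc[gene]]
        if len(hits) == 1:
            summary.tissue_specific.setdefault(hits[0], []).append(gene)

    for gname, groups in groupings.items():
        labels = list(groups)
        member: Dict[str, Set[str]] = {}
        for label, tissues in groups.items():
            panel.validate(tissues)
            cols = [t for t in tissues if t in mat.columns]
            member[label] = set(mat.index[mat[cols].any(axis=1)]) if cols else set()
        regions: Dict[frozenset, List[str]] = {}
        grouped_genes = set().union(*member.values()) if member else set()
        for gene in sorted(grouped_genes):
            key = frozenset(l for l in labels if gene in member[l])
            regions.setdefault(key, []).append(gene)
        summary.venn[gname] = regions
    return summary


def venn_counts(summary: TissueSetSummary, grouping: str) -> Dict[frozenset, int]:
    return {k: len(v) for k, v in summary.venn[grouping].items()}
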