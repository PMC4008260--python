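"""Curated flax PME/PMEI family feature tables and their summary statistics.

The packaged tables describe the 105 PMEs (60 Type-1, 45 Type-2) and 95
PMEIs annotated in the flax whole-genome assembly: mature-protein size and
isoelectric point, pro-region cleavage motifs with positions, signal-peptide
and transmembrane flags, conserved-residue counts against the structural
panels, and whether any experimental transcription evidence exists.  The
functions here recompute the family-level summaries from those row-level
features using the package's own classifiers and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .motifs import CleavageReport, SiteClass, report_from_curated
from .stats import ConservationExpressionResult, pooled_conservation_test

PME_PANEL_SIZE = 11      # 6 aromatic + 2 stabilizer + 3 catalytic
PMEI_TABLE_PANEL_SIZE = 30  # panel residues encodable from the curated table


def _read(name: str) -> pd.DataFrame:
    path = resources.files("pmekit") / "data" / name
    return pd.read_csv(str(path), sep="\t", comment="#",
                       dtype=str, keep_default_na=False)


def load_type1_pmes() -> pd.DataFrame:
    return _read("flax_pme_type1.tsv")


def load_type2_pmes() -> pd.DataFrame:
    return _read("flax_pme_type2.tsv")


def load_pmeis() -> pd.DataFrame:
    return _read("flax_pmei.tsv")


def cleavage_reports() -> List[CleavageReport]:
    """Site classification of every curated Type-1 PME."""
    df = load_type1_pmes()
    return [
        report_from_curated(row.gene, row.bm1, row.bm2, row.positions)
        for row in df.itertuples(index=False)
    ]


def site_class_counts() -> Dict[str, int]:
    counts = {c.value: 0 for c in SiteClass}
    for rep in cleavage_reports():
        counts[rep.site_class.value] += 1
    return counts


def two_site_separations() -> List[int]:
    return sorted(
        rep.separation for rep in cleavage_reports()
        if rep.site_class is SiteClass.TWO_SITE and rep.separation is not None
    )


@dataclass(frozen=True)
class PiSummary:
    n: int
    mean: float
    sd: float  # sample standard deviation


def pi_summary(which: str = "pme") -> PiSummary:
    """Mean and SD of the mature-protein isoelectric points."""
    if which == "pme":
        values = pd.concat([load_type1_pmes()["pi"], load_type2_pmes()["pi"]])
    elif which == "pmei":
        values = load_pmeis()["pi"]
    else:
        raise ValueError("which must be 'pme' or 'pmei'")
    v = values.astype(float).to_numpy()
    return PiSummary(len(v), float(np.mean(v)), float(np.std(v, ddof=1)))


def secretion_signal_counts() -> Dict[str, Tuple[int, int]]:
    """Genes with a signal peptide and/or transmembrane segment, per family."""
    pme = pd.concat([load_type1_pmes()[["sp", "tm"]],
                     load_type2_pmes()[["sp", "tm"]]])
    pmei = load_pmeis()[["sp", "tm"]]

    def count(df: pd.DataFrame) -> Tuple[int, int]:
        has = ((df["sp"] == "+") | (df["tm"] == "+")).sum()
        return int(has), len(df)

    return {"pme": count(pme), "pmei": count(pmei)}


def pme_conservation_vs_expression() -> ConservationExpressionResult:
    """Pooled conservation of the 11-residue PME panel, expressed vs not."""
    frames = []
    for df in (load_type1_pmes(), load_type2_pmes()):
        sub = df[["gene", "aromatic", "stabilizer", "catalytic", "expressed"]]
        frames.append(sub)
    allpme = pd.concat(frames)
    conserved = {
        row.gene: int(row.aromatic) + int(row.stabilizer) + int(row.catalytic)
        for row in allpme.itertuples(index=False)
    }
    expressed = {row.gene: row.expressed == "+"
                 for row in allpme.itertuples(index=False)}
    return pooled_conservation_test(conserved, PME_PANEL_SIZE, expressed)


def pmei_conservation_vs_expression() -> ConservationExpressionResult:
    """Pooled conservation of the PMEI panel residues encodable from the
    curated table (30 of the 33 analysed residues), expressed vs not."""
    df = load_pmeis()
    cols = [f"cons_g{i}" for i in range(1, 7)]
    conserved = {
        row["gene"]: sum(int(row[c]) for c in cols)
        for _, row in df.iterrows()
    }
    expressed = {row.gene: row.expressed == "+"
                 for row in df.itertuples(index=False)}
    return pooled_conservation_test(conserved, PMEI_TABLE_PANEL_SIZE, expressed)


def orientation_residue_distribution() -> List[Tuple[str, int]]:
    """Residues observed at the PMEI N-terminal orientation position."""
    counts = load_pmeis()["orientation_aa"].value_counts()
    return [(aa, int(n)) for aa, n in counts.items() if aa not in ("", "-")]
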