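"""Consolidated per-gene characterization and expression reports.

``run_characterize`` chains classification, cleavage-motif scanning,
mature-protein derivation and conserved-residue profiling into one row per
gene; ``run_express`` turns a CT well table into a delta-CT matrix with
detection summaries.  Every run can emit a machine-readable provenance block
(configuration hash and parameter versions) so identical configurations
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .classify import classify_family
from .conservation import (ResiduePanel, default_pme_panel, default_pmei_panel,
                           make_aligner, profile_members, score_panel,
                           align_to_reference)
from .expression import (DEFAULT_MIN_BIOREPS, DEFAULT_QUALITY_MIN, TissuePanel,
                         delta_ct, detect, tissue_sets, venn_counts)
from .maturation import DEFAULT_PKA, derive_mature
from .motifs import SiteClass, classify_sites, linker_region, scan_canonical
from .records import (DomainLabel, ExpressionEvidence, Family, ProteinRecord,
                      TopologyAnnotation)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fasta: Optional[str] = None
    domains: Optional[str] = None
    topology: Optional[str] = None
    evidence: Optional[str] = None
    ct_matrix: Optional[str] = None
    controls: Tuple[str, ...] = ()
    quality_min: float = DEFAULT_QUALITY_MIN
    min_bioreps: int = DEFAULT_MIN_BIOREPS
    invert_sign: bool = False
    pka: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    site_choice: str = "BM2"
    linker_margin: int = 10
    evalue_max: float = 1.0
    strict: bool = False
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_records(config: RunConfig) -> List[ProteinRecord]:
    seqs = pio.read_fasta(config.fasta)
    domains = pio.read_domain_hits(config.domains) if config.domains else {}
    topology = pio.read_topology(config.topology) if config.topology else {}
    evidence = pio.read_evidence(config.evidence) if config.evidence else {}
    records = []
    for name, seq in seqs.items():
        records.append(ProteinRecord(
            name, seq,
            domains=domains.get(name, []),
            topology=topology.get(name, TopologyAnnotation()),
            evidence=evidence.get(name, ExpressionEvidence()),
        ))
        if name not in domains:
            msg = f"{name}: no domain annotation; row emitted with blanks"
            if config.strict:
                raise ValueError(msg)
            logger.warning(msg)
    return records


def characterize_records(
    records: Sequence[ProteinRecord],
    config: Optional[RunConfig] = None,
    pme_panel: Optional[ResiduePanel] = None,
    pmei_panel: Optional[ResiduePanel] = None,
) -> pd.DataFrame:
    """One consolidated row per gene: family, mature size/MW/pI, cleavage
    motifs, topology flags, panel aggregates, evidence."""
    config = config or RunConfig()
    pme_panel = pme_panel or default_pme_panel()
    pmei_panel = pmei_panel or default_pmei_panel()
    aligner = make_aligner()
    rows = []
    for rec in records:
        assignment = classify_family(rec, config.evalue_max)
        family = assignment.family
        cleavage = None
        bm = {"bm1": "", "bm2": "", "positions": "", "site_class": "",
              "separation": ""}
        if family is Family.TYPE1_PME:
            pmei_end = max(h.end for h in rec.hits(DomainLabel.PMEI))
            pme_start = min(h.start for h in rec.hits(DomainLabel.PME))
            region = linker_region(len(rec), pmei_end, pme_start,
                                   config.linker_margin)
            hits = scan_canonical(rec.aa_seq, region)
            cleavage = classify_sites(hits, id=rec.id)
            bm["site_class"] = cleavage.site_class.value
            if cleavage.site_class is SiteClass.TWO_SITE:
                bm["bm1"], bm["bm2"] = hits[0].tetrapeptide, hits[-1].tetrapeptide
                bm["positions"] = f"{hits[0].start}-{hits[-1].start}"
                bm["separation"] = cleavage.separation
            elif cleavage.site_class is SiteClass.ONE_SITE:
                bm["bm2"] = hits[0].tetrapeptide
                bm["positions"] = str(hits[0].start)
        mature = derive_mature(rec, assignment, cleavage,
                               site_choice=config.site_choice, pka=config.pka)
        panel = None
        if family in (Family.TYPE1_PME, Family.TYPE2_PME):
            panel = pme_panel
        elif family is Family.PMEI:
            panel = pmei_panel
        agg: Dict[str, int] = {}
        if panel is not None:
            mapping = align_to_reference(rec.aa_seq, panel.reference_seq,
                                         aligner)
            profile = score_panel(mapping, panel, id=rec.id)
            agg = profile.class_counts()
        rows.append({
            "gene": rec.id,
            "family": family.value,
            "aa": mature.n_aa,
            "kda": round(mature.mw_kda, 1),
            "pi": round(mature.pi, 2),
            **bm,
            "sp": "+" if rec.topology.has_signal_peptide else "-",
            "tm": "+" if rec.topology.has_tm else "-",
            "removed": mature.removed,
            "expressed": "+" if rec.evidence.expressed else "-",
            **{f"cons_{k.lower()}": v for k, v in sorted(agg.items())},
        })
    return pd.DataFrame(rows)


def site_class_summary(report: pd.DataFrame) -> Dict[str, int]:
    sub = report[report["family"] == Family.TYPE1_PME.value]
    counts = {c.value: 0 for c in SiteClass}
    for value in sub["site_class"]:
        if value:
            counts[value] += 1
    return counts


def run_characterize(config: RunConfig, outdir: Optional[str] = None) -> pd.DataFrame:
    records = load_records(config)
    report = characterize_records(records, config)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "characterization.tsv", sep="\t", index=False)
        _write_provenance(out, config, n_records=len(records))
        if not report.empty:
            summary = site_class_summary(report)
            with open(out / "site_class_summary.tsv", "w") as fh:
                fh.write("site_class\tcount\n")
                for cls, n in summary.items():
                    fh.write(f"{cls}\t{n}\n")
    logger.info("characterized %d records", len(records))
    return report


def run_express(
    config: RunConfig,
    groupings: Optional[Dict[str, Dict[str, List[str]]]] = None,
    panel: Optional[TissuePanel] = None,
    outdir: Optional[str] = None,
):
    """Delta-CT profiles, detection summary, and optional Venn groupings."""
    panel = panel or TissuePanel()
    wells = pio.read_ct_wells(config.ct_matrix)
    panel.validate(wells["tissue"].unique())
    profiles = delta_ct(wells, list(config.controls), config.quality_min,
                        config.min_bioreps, config.invert_sign)
    calls = detect(wells, config.quality_min, config.min_bioreps)
    matrix = (profiles[profiles["detected"]]
              .pivot(index="gene", columns="tissue", values="delta_ct_mean"))
    summary = tissue_sets(calls, groupings or {}, panel)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        profiles.to_csv(out / "delta_ct_long.tsv", sep="\t", index=False)
        matrix.to_csv(out / "delta_ct_matrix.tsv", sep="\t")
        with open(out / "venn_summary.tsv", "w") as fh:
            fh.write("grouping\tregion\tcount\n")
            for gname in summary.venn:
                for region, genes in sorted(
                        summary.venn[gname].items(),
                        key=lambda kv: sorted(kv[0])):
                    label = "&".join(sorted(region))
                    fh.write(f"{gname}\t{label}\t{len(genes)}\n")
        _write_provenance(out, config, n_wells=len(wells))
    return profiles, summary


def _write_provenance(outdir: Path, config: RunConfig, **counts) -> None:
    block = {"config_hash": config.digest(), "seed": config.seed,
             "quality_min": config.quality_min, "pka": config.pka,
             **counts}
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(block, fh, indent=2, sort_keys=True)
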