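"""Readers and writers for the tabular and sequence formats the pipeline uses.

FASTA goes through Biopython.  Domain annotations come either as a simple TSV
(``id  label  start  end  evalue``) or as the per-domain tabular output dialect
of HMM search tools ('#'-comment lines, whitespace-separated columns, with the
alignment coordinates in the ali-from/ali-to columns).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import DomainHit, DomainLabel, ExpressionEvidence, TopologyAnnotation


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Identifiers are taken up to the first whitespace, as is conventional.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _looks_like_domtbl(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return len(line.split()) > 10
    return False


_LABELS = {"PME": DomainLabel.PME, "PF01095": DomainLabel.PME,
           "PECTINESTERASE": DomainLabel.PME,
           "PMEI": DomainLabel.PMEI, "PF04043": DomainLabel.PMEI}


def _to_label(raw: str) -> DomainLabel:
    return _LABELS.get(raw.upper().split(".")[0], DomainLabel.OTHER)


def read_domain_hits(path) -> Dict[str, List[DomainHit]]:
    """Read per-protein domain hits from TSV or HMM-search domain-table output."""
    hits: Dict[str, List[DomainHit]] = {}
    if _looks_like_domtbl(path):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.split()
                # domtblout: target name [0], query name [3], ali coords [17:19]
                tid, qname, evalue = f[0], f[3], float(f[6])
                start, end = int(f[17]), int(f[18])
                hits.setdefault(tid, []).append(
                    DomainHit(_to_label(qname), start, end, evalue))
        return hits
    df = pd.read_csv(path, sep="\t", comment="#")
    for row in df.itertuples(index=False):
        hits.setdefault(str(row.id), []).append(
            DomainHit(_to_label(str(row.label)), int(row.start), int(row.end),
                      float(row.evalue)))
    return hits


def read_topology(path) -> Dict[str, TopologyAnnotation]:
    """Topology TSV: id, sp (+/-), sp_cleavage_pos (int or blank), tm (+/-),
    tm_segments ('a-b,c-d' or blank)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    out: Dict[str, TopologyAnnotation] = {}
    for row in df.itertuples(index=False):
        has_sp = row.sp.strip() == "+"
        pos = row.sp_cleavage_pos.strip()
        segs = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in row.tm_segments.split(",") if part.strip()
        )
        out[str(row.id)] = TopologyAnnotation(
            has_signal_peptide=has_sp,
            sp_cleavage_pos=int(float(pos)) if (has_sp and pos) else None,
            has_tm=row.tm.strip() == "+",
            tm_segments=segs,
        )
    return out


def read_evidence(path) -> Dict[str, ExpressionEvidence]:
    """Evidence TSV: id, qpcr(+/-), est(+/-), rnaseq(+/-)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("-")
    out: Dict[str, ExpressionEvidence] = {}
    for row in df.itertuples(index=False):
        sources = set()
        if row.qpcr.strip() == "+":
            sources.add("QPCR")
        if row.est.strip() == "+":
            sources.add("EST")
        if row.rnaseq.strip() == "+":
            sources.add("RNASEQ")
        out[str(row.id)] = ExpressionEvidence(frozenset(sources))
    return out


def read_panel(path):
    """Residue panel TSV: ref_pos, ref_aa, class."""
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"ref_pos": int, "ref_aa": str, "class": str})


def read_pka_table(path) -> Dict[str, float]:
    """pKa configuration as a YAML/JSON key -> value mapping."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    return {str(k): float(v) for k, v in table.items()}


def read_ct_wells(path) -> pd.DataFrame:
    """CT matrix CSV: gene, tissue, biorep, techrep, ct, quality.

    Missing CT values (empty cells or 999-style no-amplification codes left as
    blank) come through as NaN.
    """
    df = pd.read_csv(path)
    required = {"gene", "tissue", "biorep", "techrep", "ct", "quality"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"CT matrix is missing columns: {sorted(missing)}")
    return df
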