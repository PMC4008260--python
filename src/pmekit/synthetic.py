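"""Seedable generators for every input the pipeline consumes.

The generators emulate the study design the package analyses: protein
families with planted domain architectures (signal peptide, PMEI-like
pro-region, inter-domain linker carrying cleavage tetrapeptides at controlled
spacing, PME domain carrying the conserved-residue panel at controlled
conservation rates), microfluidic CT matrices with stable endogenous
controls, per-gene/tissue abundances, dropout and low-quality wells, and
nucleotide paralog pairs evolved under the Kimura 2-parameter model at known
divergence.  Every generator records its ground truth so the expected output
of each consuming stage is computable exactly in the noiseless limit, and the
same spec + seed always reproduces byte-identical files.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .conservation import CLASS_RULES, ResiduePanel, default_pme_panel, default_pmei_panel
from .motifs import CANONICAL_PATTERN, KNOWN_NOVEL_TETRAPEPTIDES
from .records import (DomainHit, DomainLabel, ExpressionEvidence, ProteinRecord,
                      TopologyAnnotation)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Linker background alphabet: no motif-initiating residues (R, K, Q), so any
#: accidental canonical match must start inside a planted tetrapeptide; those
#: are removed by bounded rejection sampling.
LINKER_BACKGROUND = "ACDEFGHILMNPSTVWY"
CANONICAL_EXAMPLES = ("RKLL", "RRLL", "RKLR", "RELL", "RRML")
NOVEL_EXAMPLES = tuple(sorted(KNOWN_NOVEL_TETRAPEPTIDES))
_CANON_RX = re.compile("(?=(" + CANONICAL_PATTERN + "))")

SIGNAL_CORE = "AFILVWM"  # hydrophobic core of the synthetic signal peptide


@dataclass(frozen=True)
class MotifPlan:
    """Planted cleavage-site content for one Type-1 gene."""

    kind: str  # 'two_site' | 'one_site' | 'novel' | 'none'
    separation: Optional[int] = None
    tetrapeptides: Tuple[str, ...] = ()


@dataclass
class FamilySimSpec:
    n_type1: int = 12
    n_type2: int = 9
    n_pmei: int = 19
    sp_prob: float = 0.7
    #: explicit per-gene plans; None draws kinds at the family frequencies
    #: observed in flax Type-1 PMEs (25:19:3:13 one/two/novel/none).
    motif_plan: Optional[Sequence[MotifPlan]] = None
    separation_range: Tuple[int, int] = (14, 33)
    #: probability that a panel residue is left intact, per residue class
    #: (a single float applies to all classes).
    panel_conservation: object = 0.9
    panel_conservation_unexpressed: object = None
    expressed_prob: float = 77 / 105
    #: per-pair true K2P distances for CDS paralog pairs attached to members.
    duplication: Tuple[float, ...] = ()
    cds_length: int = 999
    ts_tv_ratio: float = 2.0
    linker_length: int = 45
    background_mutation: float = 0.0
    seed: int = 0


@dataclass
class SimulatedFamily:
    records: List[ProteinRecord]
    truth: pd.DataFrame
    panel_truth: pd.DataFrame
    paralog_truth: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_fasta({r.id: r.aa_seq for r in self.records},
                        outdir / "proteins.fasta")
        cds = {r.id: r.cds_seq for r in self.records if r.cds_seq}
        if cds:
            pio.write_fasta(cds, outdir / "cds.fasta")
        with open(outdir / "domains.tsv", "w") as fh:
            fh.write("id\tlabel\tstart\tend\tevalue\n")
            for r in self.records:
                for h in r.domains:
                    fh.write(f"{r.id}\t{h.label.value}\t{h.start}\t{h.end}\t{h.evalue}\n")
        with open(outdir / "topology.tsv", "w") as fh:
            fh.write("id\tsp\tsp_cleavage_pos\ttm\ttm_segments\n")
            for r in self.records:
                t = r.topology
                fh.write("\t".join([
                    r.id,
                    "+" if t.has_signal_peptide else "-",
                    str(t.sp_cleavage_pos or ""),
                    "+" if t.has_tm else "-",
                    ",".join(f"{a}-{b}" for a, b in t.tm_segments),
                ]) + "\n")
        with open(outdir / "evidence.tsv", "w") as fh:
            fh.write("id\tqpcr\test\trnaseq\n")
            for r in self.records:
                s = r.evidence.sources
                fh.write("\t".join([
                    r.id,
                    "+" if "QPCR" in s else "-",
                    "+" if "EST" in s else "-",
                    "+" if "RNASEQ" in s else "-",
                ]) + "\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.panel_truth.to_csv(outdir / "panel_truth.tsv", sep="\t", index=False)
        self.paralog_truth.to_csv(outdir / "paralog_truth.tsv", sep="\t", index=False)


def _conservation_prob(spec_value: object, cls: str) -> float:
    if isinstance(spec_value, Mapping):
        return float(spec_value[cls])
    return float(spec_value)


def _plant_panel(
    ref_seq: str,
    panel: ResiduePanel,
    q_by_class: object,
    rng: np.random.Generator,
) -> Tuple[str, List[dict]]:
    """Copy the reference, knocking panel residues out of their conserved
    class with probability 1 - q."""
    seq = list(ref_seq)
    flags = []
    for e in panel.entries:
        q = _conservation_prob(q_by_class, e.cls)
        keep = bool(rng.random() < q)
        if not keep:
            allowed = CLASS_RULES[e.cls]
            forbidden = set(allowed) if allowed is not None else {e.ref_aa}
            choices = [a for a in AA20 if a not in forbidden]
            seq[e.ref_pos - 1] = choices[int(rng.integers(len(choices)))]
        flags.append({"ref_pos": e.ref_pos, "class": e.cls,
                      "planted_conserved": keep})
    return "".join(seq), flags


def _mutate_background(seq: str, rate: float, fixed: frozenset,
                       rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if (i + 1) in fixed:
            continue
        if rng.random() < rate:
            out[i] = AA20[int(rng.integers(20))]
    return "".join(out)


def _draw_linker(plan: MotifPlan, length: int,
                 rng: np.random.Generator) -> Tuple[str, List[int]]:
    """Linker with the planted motifs and no other canonical match."""
    motifs = list(plan.tetrapeptides)
    if plan.kind == "two_site":
        sep = plan.separation
        span = 4 + sep + 4
        if span > length:
            raise ValueError(
                f"separation {sep} does not fit a linker of {length} residues")
        start1 = 1 + int(rng.integers(length - span + 1))
        starts = [start1, start1 + 4 + sep]
    elif plan.kind in ("one_site", "novel"):
        starts = [1 + int(rng.integers(length - 4 + 1))]
    else:
        starts = []
    for _ in range(200):
        bg = rng.choice(list(LINKER_BACKGROUND), size=length)
        seq = list("".join(bg))
        for start, motif in zip(starts, motifs):
            seq[start - 1:start + 3] = motif
        s = "".join(seq)
        found = [m.start() + 1 for m in _CANON_RX.finditer(s)]
        expected = sorted(st for st, m in zip(starts, motifs)
                          if _CANON_RX.match(m))
        if found == expected:
            return s, starts
    raise RuntimeError("could not place motifs without spurious matches")


def _draw_plan(rng: np.random.Generator, spec: FamilySimSpec) -> MotifPlan:
    kind = rng.choice(["one_site", "two_site", "novel", "none"],
                      p=np.array([25, 19, 3, 13]) / 60)
    return _materialize_plan(MotifPlan(str(kind)), rng, spec)


def _materialize_plan(plan: MotifPlan, rng: np.random.Generator,
                      spec: FamilySimSpec) -> MotifPlan:
    if plan.kind == "two_site":
        sep = plan.separation
        if sep is None:
            lo, hi = spec.separation_range
            sep = int(rng.integers(lo, hi + 1))
        tets = plan.tetrapeptides or (
            CANONICAL_EXAMPLES[int(rng.integers(len(CANONICAL_EXAMPLES)))],
            CANONICAL_EXAMPLES[int(rng.integers(len(CANONICAL_EXAMPLES)))],
        )
        return MotifPlan("two_site", sep, tets)
    if plan.kind == "one_site":
        tets = plan.tetrapeptides or (
            CANONICAL_EXAMPLES[int(rng.integers(len(CANONICAL_EXAMPLES)))],)
        return MotifPlan("one_site", None, tets)
    if plan.kind == "novel":
        tets = plan.tetrapeptides or (
            NOVEL_EXAMPLES[int(rng.integers(len(NOVEL_EXAMPLES)))],)
        return MotifPlan("novel", None, tets)
    return MotifPlan("none")


def _signal_peptide(rng: np.random.Generator) -> str:
    core = rng.choice(list(SIGNAL_CORE), size=22)
    return "M" + "".join(core) + "A"  # 24 residues, cleavage after position 24


def simulate_family(spec: FamilySimSpec) -> SimulatedFamily:
    """Generate a synthetic PME/PMEI family with full ground truth."""
    rng = np.random.default_rng(spec.seed)
    pme_panel = default_pme_panel()
    pmei_panel = default_pmei_panel()
    records: List[ProteinRecord] = []
    truth_rows: List[dict] = []
    panel_rows: List[dict] = []

    def conservation_for(expressed: bool) -> object:
        if not expressed and spec.panel_conservation_unexpressed is not None:
            return spec.panel_conservation_unexpressed
        return spec.panel_conservation

    plans = list(spec.motif_plan) if spec.motif_plan is not None else None
    if plans is not None and len(plans) != spec.n_type1:
        raise ValueError("motif_plan length must equal n_type1")

    def build(name: str, family: str, idx: int) -> None:
        expressed = bool(rng.random() < spec.expressed_prob)
        q = conservation_for(expressed)
        has_sp = bool(rng.random() < spec.sp_prob)
        sp = _signal_peptide(rng) if has_sp else ""
        plan = MotifPlan("none")
        motif_starts: List[int] = []
        parts: List[str] = [sp]
        offset = len(sp)
        pmei_span = pme_span = (0, 0)

        if family in ("TYPE1_PME", "PMEI"):
            region, flags = _plant_panel(
                pmei_panel.reference_seq, pmei_panel, q, rng)
            if family == "PMEI":
                for f in flags:
                    panel_rows.append({"gene": name, **f})
            parts.append(region)
            pmei_span = (offset + 1, offset + len(region))
            offset += len(region)
        if family == "TYPE1_PME":
            if plans is not None:
                plan = _materialize_plan(plans[idx], rng, spec)
            else:
                plan = _draw_plan(rng, spec)
            linker, starts = _draw_linker(plan, spec.linker_length, rng)
            motif_starts = [offset + s for s in starts]
            parts.append(linker)
            offset += len(linker)
        if family in ("TYPE1_PME", "TYPE2_PME"):
            region, flags = _plant_panel(
                pme_panel.reference_seq, pme_panel, q, rng)
            region = _mutate_background(
                region, spec.background_mutation,
                frozenset(e.ref_pos for e in pme_panel.entries) |
                frozenset(range(1, 11)), rng)
            for f in flags:
                panel_rows.append({"gene": name, **f})
            parts.append(region)
            pme_span = (offset + 1, offset + len(region))
            offset += len(region)

        seq = "".join(parts)
        domains = []
        if pmei_span != (0, 0):
            domains.append(DomainHit(DomainLabel.PMEI, *pmei_span, 1e-20))
        if pme_span != (0, 0):
            domains.append(DomainHit(DomainLabel.PME, *pme_span, 1e-30))
        topology = TopologyAnnotation(
            has_signal_peptide=has_sp,
            sp_cleavage_pos=len(sp) if has_sp else None,
        )
        evidence = ExpressionEvidence(frozenset({"QPCR"}) if expressed
                                      else frozenset())
        records.append(ProteinRecord(name, seq, domains=domains,
                                     topology=topology, evidence=evidence))
        sep = plan.separation if plan.kind == "two_site" else None
        truth_rows.append({
            "gene": name, "family": family, "expressed": expressed,
            "sp_len": len(sp), "motif_kind": plan.kind,
            "motif_starts": ",".join(str(s) for s in motif_starts),
            "motif_tetrapeptides": ",".join(plan.tetrapeptides),
            "separation": sep if sep is not None else "",
            "pmei_start": pmei_span[0] or "", "pmei_end": pmei_span[1] or "",
            "pme_start": pme_span[0] or "", "pme_end": pme_span[1] or "",
        })

    for i in range(spec.n_type1):
        build(f"T1_{i+1:03d}", "TYPE1_PME", i)
    for i in range(spec.n_type2):
        build(f"T2_{i+1:03d}", "TYPE2_PME", i)
    for i in range(spec.n_pmei):
        build(f"PI_{i+1:03d}", "PMEI", i)

    # paralog CDS pairs evolved under K2P at known distance
    paralog_rows: List[dict] = []
    members = [r for r in records]
    for k, K_true in enumerate(spec.duplication):
        a, b = evolve_pair(spec.cds_length, K_true, spec.ts_tv_ratio,
                           rng=rng)
        ia, ib = 2 * k, 2 * k + 1
        if ib >= len(members):
            raise ValueError("more duplication pairs than members to carry them")
        members[ia].cds_seq = a
        members[ib].cds_seq = b
        paralog_rows.append({"id_a": members[ia].id, "id_b": members[ib].id,
                             "K_true": K_true})

    return SimulatedFamily(
        records=records,
        truth=pd.DataFrame(truth_rows),
        panel_truth=pd.DataFrame(panel_rows,
                                 columns=["gene", "ref_pos", "class",
                                          "planted_conserved"]),
        paralog_truth=pd.DataFrame(paralog_rows,
                                   columns=["id_a", "id_b", "K_true"]),
    )


# ---------------------------------------------------------------------------
# CT matrices


@dataclass
class CtSimSpec:
    genes: Tuple[str, ...] = tuple(f"G{i+1:02d}" for i in range(10))
    tissues: Tuple[str, ...] = ("SA", "L", "R", "ECP", "EF", "SL",
                                "X", "LCP", "LF", "FB", "F", "B")
    n_bioreps: int = 3
    n_techreps: int = 3
    controls: Tuple[str, ...] = ("CTRL1", "CTRL2", "CTRL3")
    #: log2 transcript abundance per (gene, tissue); missing keys mean the
    #: transcript is absent there (wells give no CT).  None draws abundances.
    abundance: Optional[Mapping[Tuple[str, str], float]] = None
    detect_prob: float = 0.6
    abundance_mean: float = 3.0
    abundance_sd: float = 2.0
    ct_base: float = 20.0
    noise_sd: float = 0.25
    dropout_rate: float = 0.05
    low_quality_rate: float = 0.05
    seed: int = 0


@dataclass
class SimulatedCt:
    wells: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.wells.to_csv(outdir / "ct_wells.csv", index=False)
        self.truth.to_csv(outdir / "ct_truth.tsv", sep="\t", index=False)


def simulate_ct(spec: CtSimSpec) -> SimulatedCt:
    """Simulate a quality-scored CT well table plus ground truth.

    CT = base - log2 abundance + Normal(0, sd); endogenous controls sit at
    the base CT in every tissue.  Dropout wells are absent from the table;
    low-quality wells carry a quality score below 0.65.  The truth records
    each planted abundance and the expected delta-CT (CT minus the geometric
    mean of the controls, i.e. -abundance in the noiseless limit).
    """
    if not spec.controls:
        raise ValueError("at least one control gene is required")
    rng = np.random.default_rng(spec.seed)
    abundance: Dict[Tuple[str, str], float] = {}
    if spec.abundance is not None:
        abundance = dict(spec.abundance)
    else:
        for g in spec.genes:
            for t in spec.tissues:
                if rng.random() < spec.detect_prob:
                    abundance[(g, t)] = float(
                        rng.normal(spec.abundance_mean, spec.abundance_sd))
    rows = []
    for g in list(spec.controls) + list(spec.genes):
        is_ctrl = g in spec.controls
        for t in spec.tissues:
            ab = 0.0 if is_ctrl else abundance.get((g, t))
            for br in range(1, spec.n_bioreps + 1):
                for tr in range(1, spec.n_techreps + 1):
                    if rng.random() < spec.dropout_rate:
                        continue
                    if rng.random() < spec.low_quality_rate:
                        quality = round(float(rng.uniform(0.0, 0.649)), 3)
                    else:
                        quality = round(float(rng.uniform(0.65, 1.0)), 3)
                    if ab is None:
                        ct = np.nan
                    else:
                        ct = round(spec.ct_base - ab +
                                   float(rng.normal(0.0, spec.noise_sd)), 4)
                    rows.append({"gene": g, "tissue": t, "biorep": br,
                                 "techrep": tr, "ct": ct, "quality": quality})
    wells = pd.DataFrame(rows)
    truth_rows = []
    for g in spec.genes:
        for t in spec.tissues:
            ab = abundance.get((g, t))
            truth_rows.append({
                "gene": g, "tissue": t,
                "abundance_log2": ab if ab is not None else "",
                "expected_delta_ct": -ab if ab is not None else "",
                "detectable": ab is not None,
            })
    return SimulatedCt(wells, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# K2P pair evolution


def evolve_pair(
    length: int,
    K_true: float,
    ts_tv_ratio: float = 2.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[str, str]:
    """Two aligned nucleotide sequences at expected K2P distance ``K_true``.

    One sequence is drawn uniformly; the other is produced by applying the
    K2P substitution process with total expected substitutions per site
    K_true split between transitions and transversions according to
    ``ts_tv_ratio`` (expected transitions / expected transversions).
    """
    if K_true < 0:
        raise ValueError("K_true must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=length)
    if K_true == 0:
        s = "".join(anc)
        return s, s
    R = ts_tv_ratio
    a = K_true * R / (R + 1.0)        # expected transitions (alpha * t)
    b = K_true / (2.0 * (R + 1.0))    # expected per-type transversions (beta * t)
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * b) - 0.5 * math.exp(-2.0 * (a + b))
    p_tv_each = 0.25 - 0.25 * math.exp(-4.0 * b)
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    u = rng.random(length)
    which = rng.random(length)
    der = anc.copy()
    for i in range(length):
        x = anc[i]
        if u[i] < p_ts:
            der[i] = transition[x]
        elif u[i] < p_ts + 2 * p_tv_each:
            der[i] = transversions[x][0 if which[i] < 0.5 else 1]
    return "".join(anc), "".join(der)


def simulate_paralog_pairs(
    n_pairs: int,
    length: int = 1000,
    K_true: float = 0.135,
    ts_tv_ratio: float = 2.0,
    seed: int = 0,
    prefix: str = "P",
) -> Tuple[Dict[str, str], List[Tuple[str, str]]]:
    """Independent ancestor per pair, each evolved to distance ``K_true``."""
    rng = np.random.default_rng(seed)
    seqs: Dict[str, str] = {}
    pairs: List[Tuple[str, str]] = []
    for i in range(n_pairs):
        a, b = evolve_pair(length, K_true, ts_tv_ratio, rng=rng)
        na, nb = f"{prefix}{i+1:03d}a", f"{prefix}{i+1:03d}b"
        seqs[na], seqs[nb] = a, b
        pairs.append((na, nb))
    return seqs, pairs
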