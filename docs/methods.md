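# Methods

This note documents the models, parameter choices and numerical decisions
behind `pmekit`, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Family classification

Classification is presence/absence logic over externally produced domain
hits (Pfam-style PME and PMEI domains): both domains → Type-1 PME, PME only
→ Type-2, PMEI only → PMEI, neither → unclassified. Extra domains of other
kinds never change the class, and multiple hits of one domain collapse to
presence. Hits are taken as given; an optional e-value ceiling (default
1.0) filters marginal hits, because the original curation of questionable
annotations was manual and is not reproducible algorithmically. Overlapping
PME/PMEI hits on shared residues are rejected with a diagnostic rather than
resolved silently. Cross-species family proportions are compared with a
Student pooled-variance two-sample *t*-test (a Welch option exists);
identical zero-variance groups are reported as t = 0, p = 1 rather than
NaN.

## Cleavage-site model

Type-1 PMEs are matured by a subtilisin-like protease cutting at one of two
tetrapeptide sites (BM1/BM2) in the linker between the pro-region and the
PME domain. The scanner matches the canonical character classes
`[RKQ][RKEHLN][LDMI][LMAKR]` over a window restricted to the inter-domain
linker extended by a 10-residue margin on each side (full-sequence scan
available). All overlapping matches are reported.

Separation between two sites is defined as the residues strictly between
the tetrapeptides, `start₂ − start₁ − 4`; this is the definition that
reconciles recorded position pairs such as 224–242 and 246–283 with
separations of 14 and 33. With more than two hits, the pair whose
separation falls in a configurable BM1–BM2 window (default 11–33) is
chosen, tie-broken toward the most C-terminal pair.

Novel (divergent) tetrapeptides cannot be found by the pattern alone; they
are called by column-anchored voting on an alignment of one phylogenetic
group: wherever at least half the members (configurable) carry a canonical
hit anchored at an alignment column, members lacking one report the
ungapped tetrapeptide occupying that window, and members gapped across the
window make no call.

The curated flax table records four motif strings (`RKVL` twice, `RRVL`
twice) that the strict pattern rejects at the third position yet that the
original curation accepted as cleavage sites; the table also enumerates its
divergent motifs exhaustively (`RRKL`, `GRLL`, `RKVA`, `RRLW`, `REYL`,
`RRFL`). When classifying the curated dataset the package therefore treats
the enumerated set as the novel calls and every other recorded motif as an
accepted site — reproducing the published class counts (25 one-site, 19
two-site, 13 none, 3 novel-only) — while `scan_canonical` itself applies
the strict pattern unchanged. One curated two-site gene (positions 202–217)
has separation 11 under the definition above, although the published range
for two-site genes is stated as 14–33; the package reports the computed
value.

## Mature proteins, molecular weight, isoelectric point

Type-1 PMEs with at least one accepted site are cut immediately after the
tetrapeptide; when both sites are present the downstream (BM2) site is used
by default, so the entire pro-region is removed — consistent with the
mature enzyme lacking the PMEI-like segment. The choice is configurable
(BM1/BM2/none). Otherwise a predicted signal peptide (annotation input) is
removed; pro-region cleavage subsumes signal-peptide removal since the cut
site lies downstream.

Molecular weight is the sum of average (isotope-weighted) residue masses
plus one water (18.02 Da); `X` contributes a configurable 110.0 Da. The
isoelectric point is the unique root of the Henderson–Hasselbalch net
charge (positive groups N-terminus/H/K/R, negative C-terminus/D/E/C/Y),
found by bisection on pH ∈ [0, 14] to |charge| < 1e-4 (the charge is
strictly decreasing in pH). The default pKa set is N-term 8.6, C-term 3.6,
D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5, K 10.8, R 12.5 — conventional textbook
values, fully configurable, because the tool originally used for the
curated tables does not publish its internal set. Comparisons of computed
per-gene pI against curated values should therefore use a tolerance of a
few tenths of a pH unit; the family-level summaries in `flaxdata` use the
curated per-gene values directly.

## Conserved-residue profiling

Each member is mapped onto a structural reference by global pairwise
alignment (BLOSUM62, gap open 10 / extend 0.5, configurable) rather than an
MSA, keeping per-sequence scoring deterministic and order-independent.
Conservation is class-aware: catalytic, stabilizer, cysteine and
orientation positions require identity; aromatic substrate-binding
positions accept F/Y/W; polar-interface positions accept S/T/N/Q/D/E/H/K/R;
acidic-patch positions accept D/E; hydrophobic-bundle positions accept
A/V/L/I/M/F/W/C. Gaps are never conserved; identity is tracked separately.
The similarity-class memberships are declared defaults and overridable per
panel entry; E76 and D116 are filed under the polar interface (not double
counted in the acidic patch) so the panel is a set.

The default PME panel is the 11 documented residues (Q109, Q131; D132,
D153, R221; F80, Y135, F156, Y218, W223, W248 in the tomato-PME structural
numbering). The default PMEI panel contains the 26 documented residues in
mature kiwi-PMEI numbering (4 cysteines, 5 polar interface, 4 acidic patch,
12 hydrophobic bundle, K31 orientation); the original analysis counted 33
residues whose full composition is not decipherable from the published
groupings, so the panel is configurable and PMEI-side aggregates are
approximate. The packaged reference sequences are synthetic stand-ins
(filenames say so) that place the panel residues at their documented
positions: real reference sequences were not redistributable here, and all
quantitative checks run either on the curated aggregate tables or on
synthetic families built from the same stand-ins.

## Expression analysis

Wells below the platform quality threshold (default 0.65) are dropped, then
technical replicates are averaged per gene/tissue/biological replicate. The
reference for each tissue/biological replicate is the geometric mean of the
control genes' CT values — applied to CT values themselves, not linearized
quantities — and ΔCT = CT_gene − reference, so larger ΔCT means less
transcript. An `invert_sign` option emits −ΔCT as an abundance score, since
informal usage often treats larger values as more abundant. Exact
shift-invariance of ΔCT holds when the controls agree within a replicate;
with unequal controls the geometric mean makes it approximate. A biological
replicate with no valid control wells is invalid for every gene in that
tissue (warning, not an error). The standard error is the sample SD over
valid biological replicates divided by √n, reported for n ≥ 2. Detection
requires a passing well in at least 2 of 3 biological replicates (both
configurable); a biorep contributes if any technical replicate passes, as
no per-biorep technical minimum is defined. Pre-amplification is not
modelled; CT values are taken as measured. Tissue set algebra (Venn regions
over arbitrary tissue groupings, per-tissue percentages among genes
detected anywhere, single-tissue-specific lists) operates on the detection
matrix.

## Divergence dating

K2P distances count transitions (P) and transversions (Q) over sites where
both sequences have an unambiguous base (pairwise deletion), then
K = −½ ln(1−2P−Q) − ¼ ln(1−2Q); saturation (non-positive log arguments) and
empty site sets raise errors. Dating uses t = K/(2r) at the two published
plant nuclear rates 1.5×10⁻⁸ and 8.1×10⁻⁹ per site per year, reported in
MYA; their fixed ratio is 1.5/0.81 ≈ 1.852. Paralog pairing replaces an
external BLAST round trip with the package's deterministic global-alignment
score (a score-table import supports external search results); ties leave
members unpaired with a diagnostic. The published per-family dating ranges
are interpreted as the family-mean distance evaluated at both rates (a mean
K of ~0.135 dates to 4.5/8.3 MYA, ~0.192 to 6.4/11.9 MYA), since the
original summary statistic is not specified.

## Conservation vs expression

Panel positions are pooled across genes into one 2×2 table
(conserved/unconserved × expressed/non-expressed) and tested with Fisher's
exact test (two-sided, minimum-likelihood convention). Pooling treats
positions as independent — the approximation implied by family-level
pooled percentages. A table with an empty margin admits only itself under
fixed margins, so the degenerate case (e.g. both groups fully conserved) is
reported as p = 1 rather than an error. Per-residue mode builds one table
per panel position with no multiple-testing correction by default
(Bonferroni and Benjamini–Hochberg available), matching the original
per-residue analysis, which applied none.

## Synthetic data

`simulate_family` emulates the family architecture: optional 24-residue
signal peptide (Met + hydrophobic core), PMEI-like region, a 45-residue
linker carrying the planted motif plan, and a PME-like region. Motif plans
are either explicit per gene or drawn at the flax Type-1 frequencies
(25:19:3:13 one/two/novel/none), with two-site separations drawn from
14–33. Linker background excludes the motif-initiating residues R/K/Q and
is rejection-sampled until the scan recovers exactly the planted motifs.
Panel residues are knocked out of their conserved class with probability
1 − q, where q defaults to 0.9 and may differ by residue class and, for the
conservation-vs-expression round trip, between expressed and non-expressed
genes (expression probability defaults to 77/105). Ground truth records
families, signal peptides, motif plans and per-position conservation; the
same spec and seed yield byte-identical files.

`simulate_ct` plants per-gene/tissue log2 abundances (or draws them, 60%
detectable at mean 3 ± 2), sets CT = 20 − abundance + N(0, 0.25), with 5%
dropout and 5% low-quality wells by default; controls sit at CT 20. The
base of 20 mirrors the usual pass/fail expectation for pre-amplified
controls. `evolve_pair` applies the exact K2P substitution probabilities
for a branch of total length K_true split by a transition/transversion
ratio (default 2.0), so the expected estimated distance equals K_true.

What the generators do **not** emulate: realistic codon usage or indel
evolution, amplification-efficiency differences between assays, spatial
array effects, correlated biological replicates, and real sequence homology
structure (members differ from the references only at planted positions
plus optional uniform background mutation). Passing round-trip tests
therefore demonstrates the correctness of the analysis chain under the
stated noise model, not robustness to every artefact of real data.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale inputs chosen to
keep estimator checks tight but fast: 200 replicate pairs × 1000 sites for
K2P recovery, 39/43 pairs × 1000 sites for family dating, families of
40–100 genes for conservation statistics, 20 genes × 12 tissues × 3×3
replicates for CT matrices. All randomness flows through explicit
`numpy.random.default_rng` seeds; the acceptance script derives every
sub-seed from its `--seed` argument.

## Known limitations

* Domain, signal-peptide, transmembrane and localization predictions are
  consumed as annotations, never computed.
* The curated flax tables encode a single overall transcription-evidence
  flag; the per-source breakdown (qRT-PCR / EST / RNA-seq) is not fully
  recoverable from them.
* PMEI panel aggregates cover the 30 table-encodable residues of the
  original 33, so PMEI-side percentages differ from the published ones by
  about one point.
* Per-gene pI depends on the pKa set; only family-level distributions are
  asserted exactly.
* Maximum-likelihood tree inference, bootstrap support and codon-aware
  alignment are out of scope.
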