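# Methods

`mitoreorg` analyzes the reorganization of mitochondrial genomes in
frogs (and vertebrates generally): how gene order changes, what mechanism
explains the changes, and whether codon usage shows any signature of
adaptive gene positioning. This note documents the models, conventions and
numerical choices behind each stage.

## Genome model and coordinates

A mitogenome is a circular annotated molecule (`MitoGenome`): length,
optional nucleotide sequence, and an ordered list of features (13
protein-coding genes, 2 rRNAs, up to 22 tRNAs, the control region CR, the
light-strand replication origin O_L, pseudogenes, non-coding spacers).
Internally all coordinates are 0-based half-open on the circle; GenBank's
1-based inclusive convention is converted at the boundary. A feature may
wrap the numbering origin (`start > end`, end modulo length), which keeps
modular arithmetic unambiguous — the numbering origin of a circular
genome is an arbitrary choice, and every statistic in the package is
invariant under rotating it (tested property).

Gene names are normalized to MitoZoa-style tokens (`cox1`, `nad4L`,
`trnL(CUN)`, `trnS(AGY)`, `rrnS`, `CR`, `OL`) through an explicit alias
table shipped as `data/gene_names.tsv`; the two leucine and two serine
tRNA isotypes are disambiguated from an explicit `(UUR)/(CUN)/(UCN)/(AGY)`
tag or from the annotated anticodon. Unknown names are kept as
non-coding features with a warning, never dropped.

## Gene orders and classification

A `GeneOrder` is a circular token sequence (name, strand, pseudogene
flag, copy index) with rotation-invariant equality. Two reference
arrangements are built in: the vertebrate ancestral gene order (AGO) and
the neobatrachian arrangement in which trnL(CUN)–trnT–trnP–trnF form the
LTPF cluster next to the CR. Classification labels an order AGO only
when its functional tokens are rotation-equal to the ancestral reference
with no losses, duplications or pseudogenes; everything else is RGO, with
named diagnostics (LTPF cluster, intact WANCY block, trnH translocation,
trnM duplication, pseudogene/lost/duplicated gene lists). A gene
surviving only as a pseudogene is listed both as pseudogenized and as
functionally lost. Non-coding gaps of at least 30 bp (configurable)
become explicit `spacer(<bp>)` tokens; spacers and pseudogenes are
excluded from order equality and from the adjacency distance but kept as
diagnostics.

The order-difference measure is a shared-adjacency distance: the number
of strand-aware adjacent gene pairs present in one order but not the
other (symmetrized as the maximum of the two directions). It is not an
edit distance under any rearrangement model; it is a simple, oracle-
checkable dissimilarity.

## TDRL inference

Tandem duplication–random loss (TDRL) is the standard mechanism for
mitochondrial gene-order change: a contiguous tract is duplicated in
tandem, then redundant copies decay. A single event is modeled as a
duplication interval plus a per-gene, per-copy fate in {retained,
pseudogenized, deleted} with exactly one copy of each gene retained.
Deleted copies leave no token; pseudogenized copies leave a flagged
token. Given ancestral and derived linear segments (rearrangement
hotspots such as WANCY are local tracts), `infer_tdrl` returns *all*
minimal-cost single events, minimality being lexicographic: fewest
duplicated genes, then fewest non-retained copies; ties are reported,
not broken silently. The search matches the derived segment against the
two-copy merge pattern of every candidate interval (monotone subsequence
matching), which is exhaustively verified against a forward-enumeration
oracle for all segments of up to 6 genes. Segments longer than 12 genes
are rejected by default (`max_len`).

Boundary flags (`partial_left`/`partial_right`) mark events whose
silenced edge copy is compatible with a *partial* duplication of the
tract boundary — the order-level model cannot distinguish a full from a
partial duplicate, and sequence-level evidence is out of scope. Multi-
event histories are not searched; a derived segment no single event
explains is reported as unexplained (`tdrl_status`), distinct from the
identical case where no event is needed.

## Codon usage and RSCU

Codon counting uses the vertebrate mitochondrial genetic code (NCBI
table 2: AGA/AGG stop, AUA = Met, UGA = Trp; 60 sense codons). Each
annotated, non-pseudogene CDS is read in its own frame from its own
strand; terminal stop codons and incomplete terminal codons are trimmed;
ambiguous codons are skipped and counted; an internal stop flags the
gene (pseudogene suspicion) without aborting the genome. Codons are
enumerated once per gene, so nucleotides shared by overlapping genes
(atp8/atp6 style) contribute to both genes' tables; a
`dedupe_overlaps` switch instead counts each genomic codon once in the
pooled table, for the alternative reading of "counted once".

RSCU (relative synonymous codon usage) for codon c in family F of size
n_F is `x_c / ((1/n_F) Σ_{c'∈F} x_{c'}`) — the observed count over the
family mean, 1 meaning no bias. Families are the synonymous families of
code table 2 with leucine split into CUN vs UUR and serine into UCN vs
AGY, matching their two distinct tRNAs; a family with zero total is
reported as missing, not zero. These 22 families coincide with the 22
tRNA isotype codon sets, which partition the sense codons, so per-tRNA
usage sums exactly to the total codon count.

Alternative initiation codons are counted literally (not recoded to
Met): which tRNA reads position 1 is unknowable from annotation, and
literal counting is reproducible.

Between-genome codon-usage comparison is a chi-square test of
homogeneity on the 2×K pooled sense-codon table: columns zero in both
genomes are dropped; columns with expected count < 1 are pooled into a
single remainder column (configurable); no Yates correction. df = K′−1.

## tRNA position vs codon usage

The adaptive-positioning hypothesis predicts heavily used tRNA genes sit
close to the CR, where transcription initiates. The distance of a tRNA
gene is measured from the CR's 3' end to the tRNA's 5' end along the
circle in annotation (heavy-strand transcription) direction, modulo
genome length — a tRNA just upstream of the CR gets a large distance,
never a negative one (a `min_arc` switch gives the undirected
alternative). For a minus-strand tRNA the 5' end is the annotation-end
coordinate. Genomes with duplicated CRs use the first CR in genome scan
order; duplicated tRNAs use the first copy downstream of the CR 3' end;
pseudogene tRNAs are excluded. Genomes lacking a CR (e.g. partial
assemblies) are skipped with a logged reason.

One record per (genome, tRNA isotype) pairs the distance with the raw
pooled usage of the codons that isotype decodes (raw counts, not RSCU or
frequency — a frequency option exists). A full 22-tRNA complement gives
22 records per genome — 308 for a 14-genome set. Pearson (raw values)
and Spearman (average ranks, tie-aware) correlations are reported with
two-tailed p-values; pooled correlations pool raw points across genomes
rather than averaging per-species coefficients. Hydropathy classes
(hydrophobic = G, A, V, L, I, P, F, M, W, C; hydrophilic = the rest) are
used for reporting groups only and affect no statistic.

## Pairwise dS/dN (NG86)

Divergence between congeneric pairs uses the Nei–Gojobori (1986)
counting estimator with Jukes–Cantor correction, per gene on
length-matched coding sequences (no alignment is performed; simulated
pairs match by construction, real data must be pre-aligned). Synonymous
site fractions per codon position exclude changes that would create a
stop codon from the denominator; multi-difference codons are averaged
over all minimal substitution pathways, discarding pathways through
stop codons (if every pathway is discarded, all are kept and
stop-crossing steps count as nonsynonymous). `d = −(3/4)·ln(1 − (4/3)p)`;
p ≥ 3/4 raises a saturation error naming the gene, and a mid-sequence
stop aborts the gene with a flagged error rather than corrupting site
counts. ω = dN/dS is undefined (flagged) when dS = 0. Site counts obey
S + N = 3 × compared codons, and the estimator is symmetric in its
arguments (both tested properties).

Group comparisons of per-gene rates default to a two-sided Mann–Whitney
U test (rank-based, no normality assumption; Welch's t optional). The
choice is reported in output; no claim is made to reproduce any
particular published p-value, since the original test is unspecified.

## Synthetic genomes

The generator exists so every stage can be tested against recorded
ground truth. It emulates anuran-like mitogenomes: ~15–18 kb circles
with the 13 protein-coding genes at near-anuran codon counts (cox1 ≈ 516
codons; ~3,780 codons total), rRNAs of 935/1,580 bp, 68–73 bp tRNA
placeholders carrying the correct anticodon (not foldable cloverleaves —
nothing reads tRNA structure), an O_L of 32 bp, a CR built from a 60 bp
tandem repeat × 5 plus 880 bp of unique sequence, optional 62 bp
pseudogene relics (the trnS(AGY) situation), and orders taken from the
references or produced by recorded random TDRL events.

CDS sequences are drawn codon by codon: the family usage weight is
log-linear in the distance of the family's tRNA from the CR
(`weight ∝ exp(−β·distance/genome length)`), split evenly within the
family, so that at β = 0 every family has equal expected usage and the
realized distance–usage correlation is pure sampling noise. β is the
single effect-size knob; because count data cannot hit a target
correlation exactly, `calibrate_beta` grid-searches β on cheap
family-count simulations and the ledger *reports* the realized pooled
correlation. Pseudogenized or absent tRNAs keep a neutral weight — their
codons are still translated (imported tRNAs) — and no in-frame stop can
be drawn.

Congeneric partners are evolved per gene by placing Poisson numbers of
synonymous and nonsynonymous single-nucleotide substitutions (means
pS·S and pN·N, with p the Jukes–Cantor inverse of the target distance)
on distinct codons, never creating stops. One change per codon keeps the
NG86 pathway counting exact, so the realized difference counts in the
ledger match the estimator's Sd/Nd exactly, and recovered dS/dN match
the targets up to Poisson noise. Targets whose expected proportion
exceeds 0.70 are rejected as saturated (noise near the JC singularity at
3/4 makes them unrecoverable). All randomness flows from a single seed
through named substreams, and a fixed seed reproduces byte-identical
GenBank output.

What the generator does *not* emulate: realistic base composition or
strand asymmetry, tRNA/rRNA secondary structure, indels, repeat-unit
heterogeneity in the CR, within-genome rate variation, or phylogenetic
correlation among species. Passing tests therefore demonstrate that the
pipeline measures what the model generates — not that real frog
mitogenomes satisfy the model.

## Problem sizes and verification

The test suite and the acceptance script (`scripts/acceptance.py`) use:
14-genome sets for dataset cardinality (308 records), exhaustive TDRL
oracle equivalence on all segments of ≤ 6 genes (~9,700 derivations),
1,000 random tables/datasets for the RSCU and correlation identities
(errors at machine precision, bands 1e-12), 20 simulated pairs at
dS = 0.10/dN = 0.02 over ~3,780 codons (means within 10% relative), 50
neutral replicates at ~3,000 codons (mean ω within 1 ± 0.15), a 6-genome
closure check through written-and-reread GenBank (counts exact,
correlations to 1e-9), and 100 random genomes for rotation invariance.
The whole suite runs in well under a minute.
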