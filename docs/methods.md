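# Methods

`numtrisk` quantifies the risk that nuclear copies of the mitochondrial COI
barcode (NUMTs) pose to DNA-barcoding, metabarcoding and eDNA surveys. It
implements the full analysis loop on simulated data with complete ground
truth: generate an annotated mitogenome and a nuclear assembly with planted
NUMTs; screen out residual mitochondrial scaffolds; detect barcode homologs
with a local aligner; classify each call by length category, divergence and
diagnosability; and translate the category census into protocol-level
exposure and OTU-inflation figures.

## The synthetic data model

**Mitogenome.** A single circular-order sequence of 12–20 kb carrying the
13 protein-coding genes and 2 rRNAs of the canonical insect mitochondrial
gene order (tRNAs are not modelled; they contribute little length and no
reading frame). Protein-coding genes are sampled codon-by-codon from the
non-stop codons of the invertebrate mitochondrial code (NCBI table 5), so
every annotated frame is stop-free by construction. The 658 bp barcode
interval sits inside COI with a configurable codon phase (`frame_offset`)
for its first base. Intergenic spacers and rRNAs are i.i.d. uniform
A/C/G/T.

**Nuclear background.** I.i.d. random sequence with configurable GC
content. No repeat structure is modelled: the aligner's specificity is
therefore demonstrated against random background only, and real genomes —
with low-complexity tracts and transposable elements — could produce more
borderline hits than the simulations show. Everything downstream of the
hit list is unaffected by that caveat.

**Planted NUMTs.** Each NUMT is a mitogenome interval (by default
anchored on the barcode; optionally uniform over the genome), altered by:

* *Substitutions* — an exact-count site model: exactly `round(d · L)`
  distinct sites change, transitions chosen with probability
  `kappa/(kappa+1)` (default kappa = 2). The realised p-distance of a
  gap-free NUMT is therefore its nominal divergence to within one site,
  which makes divergence-recovery tests sharp. The default divergence
  range [0.02, 0.30] spans the 64–100 % identity window in which real COI
  NUMTs are observed; the lower bound keeps planted copies clear of the
  residual-mitochondrial hit filter so they are counted as NUMTs, not
  leftovers.
* *Indels* — lengths geometric(p = 0.5) truncated at 9 bp, positions at
  least 10 bp from the segment ends; a NUMT has a frameshift iff any of
  its indels has length not divisible by 3 (a consequence, not an input).
* *Premature stops* — with configurable probability a mid-segment in-frame
  codon is overwritten with TAA. Substitutions can also create TAA/TAG in
  frame by chance; the ground-truth flag `has_planted_stop` therefore
  records whether the final segment *contains* an in-frame premature stop
  (forced or emergent), because that is the property a translation screen
  can be scored against. For indel-carrying NUMTs the flag is recorded
  before indels are applied, in the source frame.
* *Duplication* — a copy-count distribution (up to 10 copies, mirroring
  observed multi-copy NUMTs); copies are identical unless a between-copy
  divergence is set, and every copy gets its own truth record sharing a
  `copy_group`.

Lengths follow a Pareto(alpha = 1) distribution truncated to
[100, 1600] bp and sampled by inverse CDF; under this model 71 % of draws
fall below 300 bp, matching the strongly short-biased length spectrum of
real COI NUMTs.

**Residual mitochondrial scaffolds.** Assemblies may carry a (partial or
padded) mitogenome copy, either labelled with "mitochondrion" in its
description or unlabelled, to exercise both screening paths.

Determinism: every generator takes a seed; identical (config, seed) yields
byte-identical FASTA and TSV artifacts, and the pipeline manifest hashes
all outputs so reruns can be checked cheaply.

## Homology search

The search is a from-scratch seed-and-extend local aligner:

1. **Seeding.** Exact 11-mer matches *plus* spaced seeds of weight 9 over
   a 15-column pattern (`111010010100110111`-style sampling;
   `SPACED_PATTERN` in `homsearch`). Contiguous-word seeding alone cannot
   meet the sensitivity this analysis needs: a 100 bp homolog at 30 %
   divergence has an appreciable chance of containing no 11 bp identical
   run at all, while spaced sampling decorrelates neighbouring offsets and
   keeps the hit probability high at the same random-match rate.
2. **Ungapped prefilter.** Each seed is extended without gaps under an
   X-drop rule (X = 15); seeds scoring below 22 are discarded. This keeps
   the number of expensive gapped extensions proportional to the number of
   genuine loci.
3. **Gapped extension.** Surviving seeds nominate a subject window sized
   to hold a full query alignment (margin 40 bp); overlapping windows are
   merged and each window is solved *exactly* by an affine-gap
   Smith–Waterman dynamic program (match +2, mismatch −3, gap open 5,
   extend 2; a length-k gap costs 5 + 2k). Within a window the best
   alignment is reported, masked, and the window re-solved, so several
   insertions landing in one window each yield a hit; a secondary
   alignment that abuts a previous one in the subject while covering a
   mostly different query interval is recognised as a broken-off fragment
   of the same insertion and suppressed. Because extension windows are
   solved to optimality by the same dynamic program that backs the
   `smith_waterman` oracle, a reported hit's score can never exceed the
   oracle score for its window — a property the test suite checks.
4. **Statistics and filters.** E-values follow Karlin–Altschul,
   E = K·m·n·exp(−lambda·S), with n the total scaffold length.
   `calibrate_karlin` fits (lambda, K) to the Gumbel distribution of
   optimal local scores of random pairs; the shipped defaults
   (lambda = 0.72, K = 0.98) come from one such fit and can be re-derived.
   Hits are kept when aligned length ≥ 100 columns, identity ≥ 0.60
   (gap and N columns excluded from both numerator and denominator) and
   E ≤ 1e-4; same-scaffold/strand hits overlapping by more than half of
   the shorter subject interval are merged, keeping the higher score.

Tie-breaks are deterministic throughout: among co-optimal end cells the
alignment minimising (subject start, query start, length) is returned, and
within a cell the traceback prefers diagonal over query-gap over
subject-gap.

The oracle aligner refuses sequences beyond 100 kb — it materialises full
DP matrices and exists for validation, not throughput.

## Mitochondrial screening

Before scanning, assemblies are cleaned in two passes. First, any scaffold
whose description contains "mitochondri" (case-insensitive, covering both
"mitochondrion" and "mitochondrial") is dropped regardless of length.
Second, unlabelled mitogenome scaffolds are detected by chunking the
reference mitogenome into ~1 kb queries and accumulating per-scaffold
alignable reference coverage at identity ≥ 0.95; scaffolds reaching 80 %
coverage are removed if at most 20 kb, and only *flagged for review* if
longer — a long mito-matching scaffold may be a mitogenome with an
expanded intergenic region or a genuine giant NUMT, and the screen stays
conservative rather than guessing. The 0.80/0.95 thresholds are package
choices, configurable at the call site. A candidate mitogenome annotation
is validated by requiring all 13 protein-coding genes exactly once, in the
canonical circular order up to rotation (reflection is not accepted), with
the strand pattern matching under the same rotation.

Hits that survive everything else but cover the entire query (within 1 bp)
at ≥ 99 % identity are removed by `filter_residual_hits`: they are either
mitochondrial leftovers the screen missed or integrations too recent to
matter at a 2 % OTU threshold.

## Classification and diagnosis

A surviving hit becomes a NUMT record with:

* **length** — the subject-side span (insertion-inclusive, the way a hit
  length reads in standard BLAST output);
* **category** — C1 (100–150), C2 (151–300), C3 (301–450), C4 (451–600),
  C5 (≥ 601 bp); calls under 100 bp are not NUMT records;
* **divergence** — 100 · (1 − identity) over comparable columns;
* **frameshift** — any maximal gap run whose length is not a multiple of
  three, each gap judged separately (two compensating gaps of 2 and 1
  restore the net frame but still each disrupt translation);
* **premature stop** — the aligned subject is translated in the
  query-anchored frame (first complete codon implied by the query's codon
  phase and the hit's query start); after a frameshift gap run the partial
  codon is discarded and translation re-anchors at the next query codon
  boundary; TAA/TAG are stops, TGA is tryptophan and AGA/AGG serine under
  table 5; a stop in the final codon is terminal, not premature.

Two guards make the diagnosis robust to alignment noise without changing
the primitive detectors' semantics (both guards are arguments, off by
default, enabled by `classify`): gap runs lying entirely within 8 columns
of an alignment end are ignored, and one codon at each end of the
translated span is excluded. Separately, a compensating pair of
equal-length gaps in opposite rows within 12 columns is re-paired ungapped
before diagnosis (`collapse_gap_pairs`): an optimal affine aligner
occasionally "explains" a substitution cluster with a register shift and
immediate shift back, and such pairs are not evidence of indels.

A record is **C5\*** when it spans essentially the full barcode
(651–661 bp), carries no IPSC, and exceeds 2 % divergence — the class that
passes every standard quality filter and inflates species counts.

**Scoring against truth.** A record matches a truth entry when both share
a scaffold and their intervals overlap by ≥ 50 % of each (greedy
one-to-one matching by decreasing overlap). With `query_len` set, the
truth-side fraction is judged against `min(planted_length, query_len)`:
a hit from a 658 bp query cannot span more of a 1.5 kb insertion, so
requiring half-coverage of the full insert would measure the matching
rule rather than the detector. Insertions whose *optimal* alignment
trims below the 100 bp reporting floor remain honest misses.

## Window counts and the COI-vs-genome-wide regression

To ask whether the barcode region is over- or under-represented among
NUMTs, the annotated gene regions (PCGs + rRNAs, concatenated in genome
order on the forward strand) are cut into non-overlapping 658 bp windows
(the trailing remainder is dropped; the default mitogenome yields 20
windows). Each window sequence is searched independently — a NUMT
straddling a window boundary may legitimately count in both windows — and
the same residual filter applies. Per species, the COI barcode count is
compared with the mean per-window count by OLS on log2-transformed values,
dropping species where either count is zero. Under uniform integration,
the slope converges to 1; the reference study (100 species, counts
log-uniform on 4–256, sources uniform) lands within [0.8, 1.2].

## Exposure, OTUs, and PCR arithmetic

A category's **exposure** to an amplicon protocol is its mean length over
the 658 bp barcode; means are interval midpoints, with C5 using the
nominal 601–661 bp span (C1 0.19, C2 0.34, C3 0.57, C4 0.80, C5 0.96, all
rounded to 2 dp to match the precision at which these figures are used).
A protocol's amplifiable NUMT count is Σ count_c · E_c over its exposed
categories — the full-barcode protocol is exposed only to C5* records,
each with exposure 1 — and the per-species figure multiplies by the number
of amplicons. Percentages (conversion, inflation, per-species) are
half-up integer rounding, so they are exact integer arithmetic across
platforms.

OTUs are single-linkage clusters (connected components of the ≤ 2 %
p-distance graph, p-distance ignoring gap/N columns pairwise). This is a
documented stand-in for the proprietary Refined Single Linkage algorithm
used by BOLD; on real data the counts may differ slightly, and the test
suite validates the clustering against a brute-force transitive closure
rather than against RESL.

The PCR models are closed-form: mitochondrial templates outnumber each
NUMT by `genome_size_ratio × mt_mass_fraction / copies` (60,000 × 0.005 /
2 = 150 for a typical insect), and a per-cycle efficiency ratio r in
favour of the NUMT multiplies the amplicon ratio by r^cycles — a 20 %
efficiency edge erases a 150-fold template deficit within 35 cycles.

## Reference study sizes

`numtrisk.studies` freezes the benchmark conditions: the recovery corpus
plants 500 NUMTs across 25 species (20 each, 3 × 30 kb scaffolds; 30 %
indel and 30 % forced-stop probability); the regression corpus uses 100
species with 2 × 6 kb scaffolds; the length study draws 10,000 samples.
These sizes keep each study's statistics stable while a full run of the
test suite completes in a few minutes on one core. Measured at the fixed
seeds: recall 0.976, precision 1.00, IPSC sensitivity 0.983 / specificity
0.985, gap-free divergence MAE 0.83 pp, regression slope 1.03.

## Known limitations

* No repeat or low-complexity structure in the nuclear background; no
  tRNAs, heteroplasmy, or within-species NUMT polymorphism.
* The aligner reports one optimal alignment per locus; co-optimal
  alternatives are resolved by fixed tie-breaks, not enumerated.
* Single-linkage is not RESL; absolute OTU counts on real BOLD data may
  shift by a few percent.
* Exposure uses midpoint category means; with empirical category means the
  protocol totals shift by a few percent.
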