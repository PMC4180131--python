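# Methods

This note documents the models, defaults and numerical choices behind
`mybfam`, and what the synthetic-data tests do and do not establish about
real data.

## Repeat model and scanner

A MYB repeat is modelled as a fixed-width position-specific scoring matrix
(PSSM). From an aligned seed of n repeats, the score of residue a at
position p is

    score(p, a) = log((count(p, a) + pc · bg(a)) / (n + pc)) − log(bg(a))

with pseudocount pc = 1 and background bg taken from the seed's residue
composition. The background-expected score of every column is
−KL(bg ‖ smoothed column) ≤ 0, so random sequence drifts to negative
scores. Unknown residues (X) score 0.

Two windows are modelled: R2 (canonical positions 1–53) and R3 (54–104).
The combined domain is treated as 104 contiguous canonical positions; the
pre-helix residues of the R3 window (54–59) play the role of the linker, and
extra residues the generator may insert between windows fall outside
canonical numbering. The shipped seed alignment is synthetic (the package's
own stand-in, `data/synthetic_seed_*.afa`) and is constructed so that the
family's documented canonical residues sit at their stated positions — D11,
C43, R46, E64, G76, R89, T90 and the highly conserved set — with tryptophan
landmarks at 7/26/45 and 60/79/98. Any user-supplied aligned FASTA can
replace it.

**Landmark rules.** A window is only a hit if every landmark position
carries an allowed residue: strict W at 7, 26, 45 and 79; {W, F, I, L, Y} at
60; {W, F, C} at 98. These are the substitutions tolerated in plant MYB
domains; the scanner records whether a hit used one (e.g. the atypical C98).

**Threshold.** No numeric cutoff is inherited from prior work, so the
default threshold is the 99.9th percentile of the per-sequence maximum
window score over 1,000 length-300 background decoys (seeded, fixed
calibration seed 2014). With the landmark requirement on top, decoy hits
are not observed in practice (0 hits on 100 decoys in the acceptance run).

**No indels within a repeat.** Windows are fixed-width; repeats with
internal insertions or deletions (rare in this family) would be missed or
shifted. Variable-length matching (profile HMMs) is deliberately out of
scope.

**Overlap resolution** is greedy by descending score with ties broken by
leftmost start — deterministic and reproducible by the brute-force oracle
used in the tests. Repeat kind (R2 vs R3) is the argmax of mean
per-position log-odds under each profile anchored at the hit start; a
margin under 0.1 nats/position is reported as unclassified. In three-repeat
proteins the repeat immediately upstream of an R2–R3 pair is relabelled
R1-like (a positional, not similarity, call).

**Family classes.** 0 hits → non-MYB, 1 → single-repeat (excluded from the
multi-repeat family), 2 → R2R3, 3 → MYB3R, ≥4 → MYB4R. A multi-repeat
protein whose full-length global-alignment identity (BLOSUM62, gap open
−10, extend −1, matches / alignment columns) to the CDC5 landmark exceeds
40% becomes CDC5-like regardless of count. The shipped CDC5 landmark is a
synthetic stand-in; supply a real CDC5 ortholog for real analyses.

## Conservation profiling

Because windows are fixed-width and landmark-anchored, same-kind repeats
already share coordinates, so the "alignment" is column stacking; a general
aligner is unnecessary for domain-level conservation and is not part of the
core (this also makes conservation exactly reproducible). Frequencies are
gap-excluded relative frequencies; information is log2 20 − entropy (bits),
without small-sample correction — matching the common logo convention.
Conservation classes: invariant (modal frequency 1), highly conserved
(≥ 0.9 by default; the cutoff is exposed because no printed threshold
exists), else variable. Logo stack heights are frequency × information.

## Motif scanning

Patterns use Prosite-style bracket notation with exact wildcard counts
(x3 = exactly three), giving the bHLH-interaction consensus a fixed width
of 20. Matching counts mismatches at fixed positions only. The S7 motif
default tolerance is 2 because the family's known positive C-terminal match
GRTSRWAMQ differs from GRTxRSxMK at two fixed positions; a variant pattern
GRTxRSxMx (under which that match is a single substitution) ships alongside,
since the intended wildcard placement is ambiguous — neither variant is
asserted as canonical. SG7-2 is searched only in the last 10 residues
("very C-terminal" is not quantified); L-S at positions 3–4 are required and
W/L at 1–2 upgrade the match tier. Diagnostic position 89 maps A →
anthocyanin-type, G → proanthocyanidin-type, I → the beet-specific C21 type;
position 98 is flagged atypical when not W and invalid when outside
{W, F, C}.

## Genome context

Coordinates are 1-based inclusive externally; minus-strand printed pairs
are normalised to start ≤ end with orientation kept in the strand field.
Tandem (sister) pairs use normalised start-to-start distance with a 105 kb
default threshold: the smallest round value that keeps the three known
sugar-beet pairs (102,964 / 4,658 / 22,148 bp) while excluding the nearest
non-pair (109,425 bp) on the printed coordinates. "un"-suffixed genes count
toward their chromosome; "rnd" scaffolds aggregate as unanchored. Gene
density is reported as Mb/gene only when chromosome lengths are supplied,
since the published "one gene every 10.5 Mb" admits several denominators.
Family shares are rounded to 2 (proteome) and 1 (TF set) decimals, the
printed precisions.

The shipped 75-gene catalogue transcribes a printed table whose extracted
text concatenates columns; two per-row exon digits (huqy, qcwx) were
ambiguous and were set to match the explicitly stated per-category totals
(53/11/4/2 over the two-repeat genes), choosing the rows whose same-clade
paralogs are all three-exon genes.

## Phylogeny and clades

Distances: p = mismatches / compared sites under pairwise deletion of gap
columns; Poisson correction d = −ln(1 − p) with p ≥ 0.95 capped at
−ln(0.05) (the correction diverges as p → 1). NJ is the classical
Q-criterion agglomeration; ties in Q break on the lexicographically
smallest cluster-label pair (a cluster is labelled by its smallest leaf),
negative branch lengths clamp to 0, and the result is the unrooted tree
with a trifurcating root. On additive matrices NJ is exact (theorem-backed;
tested to 8 taxa by path-length reproduction and cross-checked against an
independent NJ implementation).

Bootstrap resamples alignment columns with replacement; replicate r uses
the r-th pre-drawn index block of a single seeded generator, and taxa are
sorted by label before resampling, so supports are independent of input
order and parallelisation. Each original internal edge is scored by the
percentage of replicate trees containing the same bipartition.

Clade transfer: a query inherits clade X when the smallest supported
(≥ 50% by default) bipartition grouping it with at least one landmark
contains landmarks of clade X only; a landmark-containing group mixing
clades leaves it unassigned. A supported landmark-free group of two or more
queries is terminal: its members are reported as a novel-clade candidate
and not folded into the nearest labelled clade further up the tree — this
is what lets a species-specific clade sitting next to a labelled clade
remain its own group instead of being absorbed. The default input is the
104-position canonical domain block rather than a full-length alignment:
the variable C-terminus makes full-length alignments aligner-dependent,
though a user-supplied full-length alignment is accepted.

## Expression

Size factors are median-of-ratios: reference(g) = geometric mean of gene g
across samples over genes with no zero; factor(s) = median of
counts(g, s)/reference(g). Factors are defined up to a common scale — the
geometric-mean reference absorbs part of any column scaling — so
equivariance and recovery are assessed on ratio- or geometric-mean-
normalised factors. Presence defaults to normalised value > 0 (matching a
"no detected expression = black" heatmap convention); the cutoff is exposed
because published per-organ expressed tallies depend on an unstated
threshold. Clustering is centroid-linkage on log2(value + 1) rows under
Euclidean distance, global-minimum merges with lowest-index tie-breaks;
centroid linkage is not monotone and merge-height inversions are permitted.
The log2 pseudo-count of 1 handles exact zeros.

## Synthetic data

The generators emulate the statistical structure the pipeline assumes:

- **Proteomes** — planted repeat blocks (classes R2R3, MYB3R, MYB4R,
  single-repeat) inside random flanks of 15–60 residues, with per-position
  substitution rate `sub_rate`; strict landmarks never mutate and soft
  landmarks (60, 98) draw only from their tolerated sets. Decoys and flanks
  are drawn from the seed background composition rather than uniform, so
  false-positive calibration is honest. The R1 slot of three-repeat
  proteins is planted as a mutated second-repeat copy.
- **Gene models** — valid GFF3 with gene/mRNA/exon features; intergenic
  gaps default to 150–500 kb so that only explicitly requested spacings
  create tandem pairs; exon/intron blocks partition each gene span.
- **Counts** — negative-binomial with var = μ + φμ², gene base means
  log-uniform on 20–500 and dispersion φ = 0.05 by default, the magnitude
  expected when libraries come from one genotype and variation is dominated
  by counting noise rather than biological replication; organ-restricted
  genes are zeroed per their pattern.

What passing synthetic tests shows: the scanner recovers exactly what the
profile model defines as a repeat, normalisation recovers planted library
scales under the assumed mean–variance structure, and the tree machinery is
exact on additive inputs. What they do not show: robustness to repeat
indels, to proteome annotation errors, to biological replicate dispersion,
or to alignment ambiguity in real full-length proteins.

## Problem sizes used in checks

The packaged verification runs use 100 planted + 100 decoy proteins for
scanner recovery, 500 genes × 6 organs for size-factor recovery, 20 random
additive matrices of 4–8 taxa for NJ exactness, and 200 bootstrap
replicates on a 6-taxon alignment — sizes at which every check is exact or
tightly bounded while the whole suite runs in seconds.
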