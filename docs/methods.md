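# Methods

## Scope and layout

The package implements a kinome-survey pipeline — kinase identification
and classification, p-distance NJ phylogenetics, exon-phase structure
comparison, duplication detection with NG86 Ka/Ks dating, and a
differential-expression screen — driven entirely by a synthetic-genome
generator with recorded ground truth. It is laid out as an analysis
project: all computation is library code under `src/kinomevo/`, and the
numbered scripts under `analysis/` are thin narrative drivers. The
module functions and these scripts are the user interface; no console
entry points are installed.

## Identification and classification

A domain hit supports typicality only when both gates pass on that same
hit: E-value strictly below 0.01 and model coverage strictly above 1/2.
"Greater than 50%" is read as a strict inequality, so a hit covering
exactly half the model leaves a gene atypical. Genes whose hits all fail
the E-value gate are non-kinase, which makes
typical ∪ atypical ∪ non-kinase a partition of the gene universe.

Distinct kinase domains per protein are counted by greedy overlap
resolution on protein coordinates: qualifying hits sorted by ascending
E-value, a hit kept only if it overlaps no kept hit. Zero overlap
tolerance is a deliberate, conservative choice; profile hits to the same
domain region rarely abut exactly.

Subfamily assignment takes the argmax of per-subfamily bit scores, with
ties broken by the lexicographically smaller subfamily name so the
result is independent of row order. The subfamily → group catalog ships
as an editable TSV (`src/kinomevo/data/subfamily_groups.tsv`) seeded
with representative subfamilies of the seven groups; it is a lookup
surface, not a claim of completeness.

Tree representatives per subfamily follow the size rule 1 (≤ 6 members),
2 (7–30), 3 (> 30), drawn uniformly without replacement from a seeded
generator.

## Phylogeny

p-distance uses pairwise deletion: sites with a gap in either row of a
pair are excluded for that pair only. Complete deletion would discard
whole columns and, on sparse alignments, entire comparisons; pairwise
deletion keeps every pair measurable and matches one of the two
conventional treatments.

Neighbor joining is the standard Saitou–Nei agglomeration. Numerical
choices: Q-matrix ties resolved by the smallest current-index pair;
negative branch-length estimates clamped to zero with the deficit
transferred to the sibling edge (preserving the pair's summed length);
the final three nodes solved by the three-point formulas. On additive
matrices the reconstruction is exact to machine precision, which the
tests verify over random additive trees and against an independent NJ
implementation and a least-squares topology search on quartets.

Bootstrap supports resample alignment columns with replacement at the
original length, rebuild per replicate, and report the percentage of
replicates containing each internal bipartition of the full-data tree.
The survey convention is 1000 replicates; the analysis scripts use 100,
which is ample for the small synthetic trees and keeps runs fast.

The pipeline's tree stage pads representative kinase-domain sequences
to equal length with gap characters instead of aligning them; real
multiple alignment is outside the package's scope, and on synthetic
data the pseudo-alignment suffices to exercise distance, tree and
bootstrap code. Supports on such trees are expectedly low and carry no
biological meaning.

## Exon-phase structure

Intron phase is the cumulative coding length of the upstream exons mod
3, computed in translation order (exon order reversed for minus-strand
genes), so phase strings are strand-invariant. An intron is inside the
kinase domain when its coding-nucleotide position falls within
[3·(start−1)+1, 3·end] of the domain's protein span, inclusive on both
boundaries — a deterministic convention for the edge case of an intron
exactly at a domain edge. Genes whose CDS length is not a multiple of 3
are skipped. Conserved-structure groups are exact matches on
(subfamily, phase string); intron-less genes (empty string) join groups
only when explicitly allowed, because an empty fingerprint carries no
positional signal. Published fingerprints sometimes contain a dash
(e.g. "0020–200") whose semantics are not defined anywhere usable; this
package emits undashed strings.

## Duplications and Ka/Ks

Homology pairs are kept at E ≤ 1e-100 (the threshold is stated without
a comparator in the surveys that use it; ≤ is the permissive reading),
canonicalized and deduplicated. Gene ranks are computed over **all**
annotated genes per chromosome, not kinases only — tandem adjacency and
collinearity are properties of the whole gene order.

Tandem clusters are connected components of links between homologous
genes on the same chromosome at rank distance ≤ max_gap (default 1,
strictly consecutive). Collinear blocks chain homology anchors by
O(m²) dynamic programming over (rank_a, rank_b), separately for same
and inverted orientation, requiring strict monotonicity and rank gaps
≤ 25 on both axes, with blocks of fewer than 5 anchors discarded —
MCScanX-like defaults. Best chains are extracted iteratively; ties on
anchor count prefer the smaller total rank span. Two planted blocks
closer than the rank-gap limit on both axes will legitimately merge
into one chain; the generator's demo configurations therefore space
planted blocks more than 25 ranks apart.

NG86: per codon, each position contributes (synonymous one-step
changes)/3 synonymous sites; changes creating a stop codon count as
nonsynonymous, so s + n = 3 exactly. Between codons, differences are
averaged over all orderings of the differing positions (1, 2 or 6
pathways); pathways through stop codons are skipped with
renormalisation, and in the rare case that stops block every pathway,
all pathways are used with steps into or out of a stop counted as
nonsynonymous. Rates use the Jukes–Cantor correction
K = −(3/4)·ln(1 − (4/3)·p); p ≥ 3/4 is reported as saturated with an
undefined rate. Site counts are averaged over the two sequences; gap or
ambiguous codon columns are dropped pairwise.

Ks epochs are half-open bins: [0, 0.1) tetraploid-scale, [0.4, 0.6) the
recent whole-genome duplication, [0.6, 3.0) ancient, otherwise
unassigned — every defined Ks maps to exactly one label. A collinearity
event shows single gene correspondence when neither member appears in
any other retained pair.

## Expression

RPKM = count / ((gene length/10³) · (library size/10⁶)) with the
library size taken as the column sum of the supplied matrix (the true
mapped-read total is unavailable without alignments). Fold change is
the ratio of group means on the normalised scale with a pseudo-count of
ε = 1 (zero-safe, symmetric: 0/0 gives FC 1). The screen retains genes
with |FC| > 1.5 on the linear scale and two-sided Welch p < 0.01 on
log2(RPKM + 1), with p-values raw by default and an optional
Benjamini–Hochberg mode. The Welch test is a documented substitution
for empirical-Bayes moderated statistics (limma/DESeq2-style): the
package's claims concern recovery of planted effects under its own
generator, not replication of those estimators. Note that RPKM is not
composition-robust: when a large fraction of genes is differentially
expressed, library-size normalisation shifts all fold changes; the demo
config plants DE in 10% of genes for this reason.

## Synthetic-data generator

The generator emulates the study design the pipeline expects, with
every quantity a pure function of the config seed:

- Multi-chromosome gene orders with fixed intergenic gaps, so rank
  order equals coordinate order. Coordinates are 1-based inclusive;
  GFF3 carries gene/mRNA/CDS only, one mRNA per gene.
- Exon structure is deterministic per subfamily (lengths and the
  kinase-domain span derived by hashing the subfamily name), so
  subfamily members share a phase fingerprint within and across
  simulated species — the conservation signal the structure stage
  detects. Intron lengths vary freely.
- Duplicates (tandem members, collinear anchors) are made by
  `evolve_duplicate`: single-nucleotide proposals accepted when they
  move the NG86 difference counts toward targets derived from the
  requested Ks (and Ka = ratio·Ks, ratio default 0.3, a purifying-
  selection regime) via the inverse Jukes–Cantor map on the source's
  site counts. Using the downstream estimator's own units guarantees
  measurability; for 500-codon genes the measured Ks lands within a few
  hundredths of the target. Targets beyond JC saturation raise.
- Hit tables give typical genes one qualifying hit per planted domain,
  atypical genes only coverage ≤ 0.5 hits, and some non-kinase genes a
  high-coverage hit with a failing E-value, so the joint gate is
  exercised. Score tables rank the true subfamily highest.
- Homology tables contain planted pairs far below the filter, optional
  decoy pairs that pass the filter (default 5% in the stress configs),
  and weak pairs above it.
- Counts are negative-binomial with lognormal base means
  (median 150, σ = 1), gene dispersion default 0.05 (0.01 in the
  "low-dispersion" power configs, Poisson at 0), n = 4 samples per
  group, and planted log2 fold changes of ±2 on selected typical
  kinases.

What the generator does **not** emulate: realistic HMMER score
distributions, alignment uncertainty, annotation errors, multi-isoform
genes, GC/codon-usage structure, overdispersion heterogeneity, or real
chromosome scales. Passing tests therefore demonstrate algorithmic
correctness and recovery under controlled conditions, not performance
on real genomes.

## Problem sizes

The analysis scripts run two 120-gene genomes end to end. The heavier
recovery computations use 2 × 1000-gene genomes (collinearity with
decoys; expression error rates) and 400 duplicate pairs of 500 codons
(Ks-epoch dating), sizes at which every recovery statistic is stable
across seeds while a full run stays under ten seconds.

## Known limitations

- The pseudo-alignment in the tree stage (above) is a placeholder for a
  real MSA; p-distances between unrelated padded sequences saturate.
- NG86 with JC correction underestimates Ks under strong
  transition/transversion bias; the generator proposes substitutions
  uniformly, so the estimator and generator are consistent by
  construction.
- The collinearity chaining is a single-pass greedy extraction of DP
  chains; it does not implement MCScanX's full scoring, e-value model,
  or quota logic.
- `single_correspondence` is computed over retained anchor pairs; with
  decoy homology it can dip below 1 even when all blocks are correct.
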