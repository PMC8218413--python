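# Methods

This note records the models implemented in `aaapsurvey`, the parameter
choices that matter, the numerical conventions, and what the synthetic-data
validation does and does not establish.

## Protein characterization

Molecular weight is the sum of average-isotope residue masses plus one
water (18.01524 Da). Ambiguity codes (B, Z, J, X; U as selenocysteine)
contribute the mean mass of their candidate residues with a warning rather
than failing — a deliberate graceful-degradation choice for annotation
pipelines that emit them.

The isoelectric point solves net charge = 0 where the charge is a
Henderson–Hasselbalch sum over D, E, C, Y (acidic), H, K, R (basic) and the
two termini. The charge is strictly decreasing in pH, so bisection on
[0, 14] converges to a unique root; the stopping tolerance is 0.002 pH,
well inside the 0.01-pH agreement demanded of it against a 10⁻⁴-resolution
grid-scan oracle. The default pK set is Bjellqvist's (the set behind the
ExPASy ProtParam tool); EMBOSS and Lehninger sets are selectable
(`pk_set=`). Different pK sets shift pI by up to ~0.5 pH, so published pI
values are only reproducible to within the uncertainty of the (unstated)
tool version that produced them — the packaged family table is therefore
treated as fixture data, not a recomputation target, at the sequence level.

Transmembrane segments come from a Kyte–Doolittle sliding window: a centre
position qualifies when the mean hydropathy of its 19-residue window is
≥ 1.6; runs of qualifying centres are widened to full windows and merged.
This is an intentionally transparent surrogate for trained topology HMMs:
counts correlate with published TM counts but do not exactly reproduce
them, which is why table-level tests use the printed counts and
sequence-level tests use constructed hydrophobic/polar sequences. Window
must be odd (centred) and ≥ 9; both window and cutoff are arguments.

Family summary percentages (basic: pI > 7.0; single-exon; 8–11 TM) are kept
at full precision internally and rounded half-up only for report output
(0 decimals for the basic-protein percentage, 2 elsewhere, matching the
precision of published family tables).

## Phylogeny

Distances use the Poisson correction d = −ln(1 − p) on the proportion p of
differing residues. "Partial deletion" is implemented as a site-coverage
rule: a column is kept when gap-free in ≥ 95% of sequences (the common
default in distance phylogenetics GUIs; configurable), and each pair is
compared only over kept columns where both are ungapped. p ≥ 1 marks a pair
saturated (infinite distance); tree building refuses saturated matrices
rather than guessing.

Neighbor-joining follows Saitou–Nei: join the pair minimizing
Q(i,j) = (r−2)d(i,j) − R_i − R_j, with branch lengths
L_i = d/2 + (R_i − R_j)/(2(r−2)). Ties in Q are broken by the
lexicographically first index pair, making the tree a deterministic
function of the input order. Negative branch-length estimates (possible on
non-additive matrices) are clamped to zero with the deficit transferred to
the sister edge, preserving the joined pair's distance. The final three
nodes are resolved by the three-point formulas, leaving a trifurcating
root — i.e., an unrooted tree.

Bootstrap supports resample alignment columns with replacement (single NumPy
generator seeded by the caller; indices drawn independently per replicate),
rebuild the tree by the same NJ path, and report for each internal edge of
the reference tree the percentage of replicates containing its bipartition.
Replicates whose resampled distances saturate are dropped from the
denominator. Subfamily assignment gives each unlabeled leaf the majority
label of the smallest bipartition side containing it and at least one
labeled reference, breaking vote ties by nearest patristic reference.

## Duplication detection

Tandem: two family members qualify when they share a chromosome, are
separated by at most `max_sep` = 5 intervening genes, and their protein
similarity exceeds `min_sim` = 50% strictly. "Separation" counts intervening
genes (ordinal gap − 1), not index distance — the criterion's wording is
ambiguous, and this reading is pinned by boundary tests (5 intervening
qualifies, 6 does not; similarity exactly 50.0 does not). Qualifying pairs
are merged into groups by transitive closure (union-find), so groups are
disjoint and the relation symmetric.

Similarity is the percentage of alignment columns whose residue pair is
identical or scores positively under BLOSUM62, over the full alignment
length (gap columns in the denominator), computed on a global
Needleman–Wunsch alignment with affine gaps (open 10, extend 0.5; a gap of
length L costs open + (L−1)·extend, end gaps penalized). Published
similarity figures for specific pairs were produced by an unstated method
and are treated as descriptive, not recomputation targets.

Segmental: anchor hits (homologous gene pairs above a similarity floor,
default 50%) are chained per chromosome pair by dynamic programming into
runs whose ordinals are strictly monotone on both chromosomes (same or
inverted orientation), with consecutive-anchor gaps ≤ `max_gap` = 25 genes.
Chains shorter than `min_block` = 5 anchors are discarded; overlapping
chains are resolved greedily by score. Scoring is simplified relative to
MCScanX's full model — unit anchor score minus a small linear gap penalty
(0.01/gene, which only breaks ties toward compact chains) — the
min-block/max-gap defaults are MCScanX's.

Classification labels a family gene *tandem* if it sits in any tandem
group, else *segmental* if it appears as an anchor of a retained block;
a gene matching both is labeled tandem with a logged warning. The summary
percentage is 100 × duplicated/total.

## Selection and dating (NG86)

Site counts: each codon position contributes one site, split by the
fraction of its non-stop single-nucleotide changes that are synonymous, so
S + N = 3 exactly for every sense codon (TTT: S = 1/3; TGG: S = 0).
Mutants creating stops are excluded from the denominator — this convention
(rather than counting them as nonsynonymous) affects the third decimal of
S at most and is fixed by tests.

Differences: codons differing at k positions average Sd/Nd over the k!
mutation orderings whose intermediates are not stops; if every ordering
passes through a stop (impossible for 1–2 differences between sense codons,
rare for 3), all orderings are used. Pairwise comparison skips codon
columns containing a gap or stop (count logged), takes S as the mean of the
two sequences' site totals, and corrects pS = Sd/S and pN = Nd/N with
Jukes–Cantor, d = −(3/4)ln(1 − (4/3)p); p ≥ 3/4 is reported as a
non-finite, flagged rate. ω = Ka/Ks is undefined (NaN) when Ks = 0.

Selection calls: ω < 1 purifying, ω > 1 positive, |ω − 1| ≤ 0.01 neutral
(band configurable), non-finite → undetermined. Dating uses
T = Ks/(2λ), λ = 6.96 × 10⁻⁹ synonymous substitutions/site/year, reported
in Mya. Report output is rounded half-up to two decimals, but dating always
uses unrounded Ks internally; note that inverting printed times generally
does *not* reproduce printed Ks values beyond their two decimals, which is
why date checks against published tables compare the formula's consistency
rather than re-rounded inputs.

NG86 was chosen over ML codon models because the S-sites/N-sites columns of
published paralog tables are NG86-style output; transition/transversion
weighting (modified NG) and codeml-style ML dN/dS are out of scope.

## Expression and promoters

The display transform is log₁₀(x + 1) on nonnegative RPKM/FPKM values.
Detection calls use the raw scale: detected at ≥ 1 in at least one (any) or
all conditions, highly expressed at ≥ 10, thresholds inclusive and
configurable. Clustering is average-linkage agglomeration on 1 − Pearson
correlation across conditions, cut into k = 3 flat groups — standard
expression-heatmap practice; published heatmap gene orders depend on
unstated clustering parameters and are not reproduction targets, so
validation is group recovery on synthetic archetypes. Constant-profile
genes (undefined correlation) fall back to Euclidean distance with a
warning.

Promoters are the 2,000 bp upstream of the annotated gene start (a common
plant-promoter convention; length configurable), reverse-complemented for
minus-strand genes and truncated with a warning at chromosome edges.
The cis-element dictionary ships as editable data
(`data/cis_elements.tsv`) with consensus IUPAC patterns for the ten named
stress/hormone elements; patterns are configuration, not ground truth,
since element databases match by unpublished internals. Scanning is exact
IUPAC matching on both strands with all overlapping occurrences reported
(regex lookahead); note that complementary elements (TGACG/CGTCA) each
produce a hit on opposite strands of one occurrence, so per-gene totals
count strand-resolved matches.

## Synthetic data and what the tests show

The codon simulator evolves two lineages independently by single-nucleotide
proposals (uniform site, uniform alternative base), accepting synonymous
changes always and nonsynonymous ones with probability ω (reciprocal rule
for ω > 1), rejecting stops, until accepted synonymous substitutions per
synonymous site reach Ks/2 per lineage. It has no transition/transversion
bias, no codon-usage bias, and no indels; it exists to give NG86 a
controlled realized dN/dS, and the recovery experiment (50 replicates,
1,500-nt ancestors, Ks 0.4, ω ∈ {0.15, 0.3, 1.0}; mean ω̂ within 0.1 of
truth) validates the estimator under its own assumptions, not against real
mutational processes.

The genome generator lays out tandem arrays (spacing within the detector
threshold), segmental blocks (a gene run copied to another chromosome at
low divergence), spaced singletons, and non-homologous random background
genes, then emits genome/CDS/protein FASTA, GFF3 and a truth table; all
generators are pure functions of (spec, seed). Detector validation demands
exact truth recovery (precision = recall = 1) on 20 seeded genomes whose
planted events respect the thresholds with margin — it shows the detectors
implement their definitions, not that the thresholds are biologically
optimal. Real genomes add fragmented annotations, pseudogenes and partial
homology that these genomes deliberately lack.

Problem sizes in the test suite (eight-gene backgrounds, 300-codon family
ancestors, 20 bootstrap/200-replicate settings) are chosen as desk-scale
configurations that exercise every code path; all thresholds tested are the
pipeline defaults.

## Known limitations

- TM counts are hydropathy-based and will not match trained-HMM predictions
  residue for residue.
- pI depends on the pK set; cross-tool agreement is ~0.1–0.5 pH.
- The collinearity chainer's scoring is a simplification of MCScanX; on
  dense paralogy networks block boundaries may differ.
- NG86 with Jukes–Cantor underestimates rates at high divergence and flags
  saturation rather than extrapolating.
- The pipeline's phylogeny stage uses equal-length family proteins as
  aligned when no MSA is supplied (true for the indel-free simulator);
  real families require an externally computed multiple alignment.
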