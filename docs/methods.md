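# Methods

This note records the models, procedures and numerical choices behind each
stage of the pipeline, what the synthetic data does and does not emulate,
and the known limitations.

## Domain identification

Domains are detected with ungapped log₂-odds PSSMs built from a seed
alignment (pseudocount 1, uniform 1/20 background); a protein's score is
the maximum over all windows, and unknown residues (X) score 0. A protein
shorter than the profile is a no-hit flagged "too short". This is a
deliberate simplification of profile-HMM search: no position-specific gap
states, no local/glocal envelope — adequate for a compact, highly conserved
domain like the ~59-residue MADS box, not for domains with large indels.

Two threshold calibrations are provided. `calibrate_threshold` is the
classic empirical null: the score quantile (default 99th) of shuffled
copies of a background sequence. The pipeline instead uses
`calibrate_threshold_max`: the null **maximum** over 1,000 shuffles of a
5×-tiled consensus. Tiling matters because a real scan takes a maximum
over many windows; a single-window null underestimates that extreme and
can pass long random sequences. Genuine domain instances score several
times above either threshold, so the conservative choice costs no
sensitivity here.

Candidate bookkeeping keeps two totals on purpose: the *pooled* total (sum
of the per-search list sizes, the number a survey reports when it says its
searches "identified a total of N genes") and the distinct-id *union*.
The non-redundancy filter keeps high-confidence genes and collapses
repeated ids; the rule is exposed as a function because published surveys
rarely state the exact reduction from pooled candidates to the final set.

Protein statistics: molecular weight uses average residue masses (one
water added), reported in kDa. The isoelectric point solves net charge = 0
by bisection to |charge| < 10⁻⁴ over pH 0–14, with the EMBOSS pKa set
(N-term 8.6, C-term 3.6; K 10.8, R 12.5, H 6.5; D 3.9, E 4.1, C 8.5,
Y 10.1). pI is monotone under appended charged residues (property-tested).

## Phylogenetics

Pairwise protein alignment is optimal global alignment with BLOSUM62 and
affine gaps (open 10, extend 0.5, end gaps penalized). Distances use the
Kimura protein correction d = −ln(1 − p − 0.2p²) over columns ungapped in
both rows; when the argument is ≤ 0 the scalar routine flags saturation
and returns ∞, while the matrix routine caps at 10.0 so neighbor-joining
stays finite (the cap only affects pairs already beyond ~85% mismatch).

The multiple alignment is a center-star progressive merge: the center is
the sequence with the greatest summed pairwise score; others are aligned
to it and gap columns are propagated. Center-star is exact for the star
topology only; to avoid its projection artifacts between the two protein
architectures, the pipeline aligns and builds trees for the M-type and
MIKC-type sets **separately** (as MADS surveys do), then detects homeolog
groups per tree.

Trees are neighbor-joining with two determinism rules: among minimal-Q
pairs the lexicographically smallest cluster-name pair is joined (clusters
named by their smallest leaf), and negative branch lengths are clamped to
zero. On additive matrices NJ returns the generating topology and branch
lengths exactly (tested against brute-force minimum-evolution enumeration
up to 6 taxa). Support is the Felsenstein bootstrap: columns resampled
with replacement, NJ per replicate, support = % of replicates containing
each internal-edge bipartition. 100 replicates by default — coarse (1%
granularity) but inside the run-time budget; the count is configurable.

Subfamily assignment is nearest-reference by global alignment score
against labeled exemplars, with ties across subfamilies reported as
ambiguous rather than resolved silently. Superclade (M vs MIKC) follows
from the subfamily. The FLC vs MIKC\* diagnostic maps residues at MADS-
domain alignment positions 30/34/50: (E, Q, A|G|S) → FLC-like, (K, E, P) →
MIKC\*-like, anything else (including gaps) indeterminate. Positions are
defined in the packaged reference alignment frame; a study using a
different alignment frame must re-index rather than assume ours matches.

## Homeolog groups and balance

A homeolog group is the largest clade of a midpoint-rooted tree that (a)
has bootstrap support strictly above the threshold (default 90), (b) is
pure in subfamily, and (c) contains at most one gene per subgenome after
merging genes linked by known same-subgenome duplicate pairs. The scan is
top-down: an invalid or unsupported clade is descended into, genes landing
in no qualifying clade are "undetermined", and singleton leaves never form
groups. The whole-tree clade counts as trivially supported so a tree that
is entirely one subfamily still yields its group.

The circularity between homeology (which needs duplicate exemptions) and
duplicate calling (which needs homeolog groups) is broken by a structural
fact: two genes on the *same* subgenome can never be homeologs. The
pipeline first collects same-subgenome pairs at ≥ the identity threshold,
feeds them to the group scan as exemptions, and only then calls duplicates,
exempting different-subgenome pairs that share a group.

Balance: a group is balanced iff its members cover subgenomes {A, B, D},
unbalanced if one or two are missing, undetermined if all members are
unplaced (chromosome U; U genes count toward no subgenome). The balance
table reports per subfamily: total (balanced + unbalanced members),
undetermined members, duplication presence, and an exception flag for
subfamilies with duplications despite fully balanced homeologs.

Raising the support threshold can only move genes toward undetermined,
never the reverse (property-tested monotonicity).

## Duplication and segments

CDS identity comes from global nucleotide alignment (match +1, mismatch
−1, gap open 5, extend 0.5): identity = matches / aligned columns with
terminal gap columns excluded and internal gaps counted as mismatches;
coverage = ungapped overlap / shorter CDS length. A minimum coverage of
0.5 replaces a database-size-dependent E-value cut. Pairs are called at
identity ≥ 90% (inclusive; pairs exactly at the threshold carry a boundary
flag) and non-homeologous status. Note that duplicate calling is a
pairwise relation: several copies of one source gene yield all their
mutual pairs, so called pairs can legitimately outnumber duplication
events; the non-redundant duplicated-gene count is reported alongside.

Typing: same chromosome → tandem, different placed chromosomes →
segmental, any U gene → unplaced unless every placed partner shares one
chromosome, in which case the U gene is inferred onto it (flagged).
Segments follow the R1 | R2a | C | R2b | R3 partitioning per chromosome;
a gene sits in the segment containing its midpoint; R1/R3 are distal,
R2a/C/R2b central; pair categories are distal-telomeric (both distal),
sub-telomeric (mixed), proximal (both central).

## Ka/Ks, dating, selection

Nei–Gojobori (1986) with equal pathway weighting and Jukes–Cantor
correction, no transition/transversion weighting. Site fractions per
codon: at each position, synonymous one-step mutants divided by the count
of non-stop one-step mutants; n = 3 − s; site totals are averaged between
the two sequences. Differences: averaged over all minimal mutational
pathways, pathways through stop codons excluded; in the rare case every
pathway is stop-blocked, all pathways are used with stop-entering steps
counted as nonsynonymous, and the pair is flagged. Codon alignments come
from the protein alignment back-translated onto the CDS; any codon column
gapped in either sequence is dropped. Saturation (JC argument ≤ 0) leaves
the rate undefined and the pair flagged; such pairs are excluded from
quartile summaries with counts reported rather than silently imputed.

Dating: T = Ks/(2r), r = 6.5×10⁻⁹ substitutions/synonymous site/year by
default (configurable), reported in MYA. Selection: ω > 1 positive, < 1
purifying, = 1 neutral, undefined when Ks = 0 or saturated. Superclade
summaries give Q1/median/Q3 of Ks, ω and T plus the percentage of
defined-ω pairs under each regime.

## Expression

A gene is expressed iff any condition exceeds 0.0 log₂ TPM (strict). The
published rule only pins down "< 0 → not expressed"; values in [0, 0.2)
are a dead zone in the source tabulations, so the observed minimum
expressed value is reported for comparison instead of inventing a second
threshold. Clustering is Lloyd's algorithm on raw rows (no z-scaling),
Euclidean, best of 5 restarts by within-cluster sum of squares, 1,000
iteration cap, per-run seeds spawned from the master seed, empty clusters
re-seeded from the globally farthest point. WCSS is asserted non-
increasing on every iteration without an empty-cluster repair. All
condition columns are used by default; a grouping can be applied upstream
by averaging columns before clustering.

## Synthetic genome: what it emulates, what it does not

The generator plants, per subfamily, one or more homeolog units with a
declared subgenome pattern. All proteins descend from two superclade
ancestors (M: MADS domain + C-terminal region, ~190 aa; MIKC: MADS +
intervening region + K-box + tail, ~225 aa) built on shared MADS/K-box
consensus sequences, so alignments stay informative across subfamilies.
Divergence is applied on the CDS by the codon mutation model: expected
synonymous/nonsynonymous difference counts are the Jukes–Cantor inverses
of the target Ks and ω·Ks times the sequence's site totals, drawn as
Poisson counts and applied as categorical choices from precomputed
synonymous/nonsynonymous (never stop-creating) single-nucleotide mutant
sets. Defaults: subfamily divergence 0.18 aa, between-unit Ks 0.5,
within-triad Ks 0.03 (≈98.5% CDS identity, wheat-homeolog-like), 13
balanced + 7 unbalanced units over 16 subfamilies, 10 tandem + 10
segmental duplications at Ks 0.04–0.05 with ω spanning 0.2–1.5, 43% of
genes silenced in the expression matrix (so ~57% are expressed by
construction), K-means truth clusters on well-separated base levels.

Planted tandem copies share the source's chromosome and segment; planted
segmental copies go to a different chromosome group on the *same*
subgenome, which guarantees they can never be mistaken for homeologs.
Decoy genes (low-confidence domain-bearing fragments and high-confidence
non-family proteins) exercise the identification filters.

Not emulated: introns and intergenic sequence, indel evolution (all
within-superclade proteins are equal length), codon-usage bias, gene
conversion between homeologs, cross-subgenome segmental duplication,
expression correlated with Ka/Ks, and any real sequence content — the
packaged consensus and reference sequences are synthetic, generated from
the master seed. Passing recovery tests therefore demonstrates the
pipeline's correctness under clean, well-separated conditions; they do not
certify performance on real annotations, where confidence labels, partial
genes and alignment ambiguity dominate. Real-mode runs accept user
FASTA/TSV inputs and user-supplied profile seed alignments and reference
exemplars.

## Problem sizes and determinism

Default study conditions: 73 family genes (53 triad members + 20 duplicate
copies), 21 chromosomes, 100 bootstrap replicates, expression over 16
conditions, Ks/ω recovery grid of 3×3 cells × 50 replicate pairs of 300
codons. One full pipeline run takes ~20 s on one CPU; the whole test suite
~30 s. Every stage draws from numpy Generators seeded from one master
seed; reruns are byte-identical, and tree tie-breaks and traceback orders
are pinned so topologies are reproducible across platforms.
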