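# Methods

This note records the models, numerical choices and limitations behind
each stage of the discovery workflow, in the order the pipeline runs them.

## Data model and coordinates

Genes are stored with 0-based half-open coordinates; all file dialects
(gene-table TSV, GFF3) are 1-based inclusive and converted at the I/O
boundary. `rank` is the 0-based position of a gene along its contig by
start coordinate and is the unit of all window arithmetic — windows are
positional, not base-pair, and strand-agnostic. Domain annotations are an
external input (Pfam-style accession + E-value per gene), consumed with a
configurable ceiling (default E ≤ 1e-5) wherever "matches a known domain"
is tested; the package never scans domains itself, which keeps it free of
bundled databases while preserving the semantics of the filter.

## Windows and operons

A window holds up to `radius` genes (default 10) on each side of an
anchor, truncated at contig ends and never crossing contigs. The operon
context is the maximal run of window genes contiguous with the anchor in
rank whose consecutive members lie on the same strand (configurable) with
intergenic gaps ≤ 150 bp — the standard prokaryotic heuristic. The operon
subset only affects the operon-restricted variant of the neighbor
statistic; discovery always uses the full window.

## Candidate rules

The five-rule filter: length < 170 aa (strict), no domain annotation at
the E-ceiling, predicted signal peptide, CXXXC-type motif, C-terminal PP
motif (within the last 15 residues). The motif scanner treats pattern X as
any residue; an X in a protein never satisfies a literal pattern residue.
By default the motif must fall (by its center) in the central 20–80 % of
the protein, reflecting where the family's conserved cysteines sit;
configurable off.

The signal-peptide call is a deterministic tripartite heuristic rather
than a neural predictor: a cleavage position c ∈ [15, 40] is accepted if
(i) the n-region (residues 2–5) carries a K/R, (ii) some 8-residue window
within residues 6..c−4 has mean Kyte–Doolittle hydropathy ≥ 1.6, and
(iii) residues c−2 and c are small (A/G/S/T; the A-X-A rule). The smallest
valid c wins; the score is the best window hydropathy. The heuristic is
transparent and reproducible but weaker than modern predictors on real
sequences; externally computed calls can be supplied per gene via TSV and
take precedence. Proteins shorter than 25 residues are never called.

## Alignment

Pairwise alignment is affine-gap Gotoh DP (numba kernels) with BLOSUM62
and BLASTp-default penalties (open 11, extend 1; a gap of length k costs
11 + k). Traceback ties prefer diagonal > up > left, making outputs
deterministic. Percent identity is identical columns over alignment
length, gaps counted in the denominator — the conservative convention used
for the 90 % collapse threshold.

The progressive aligner builds a UPGMA guide tree on k-mer distances
(k = 3; distance = 1 − shared/smaller set) and merges blocks by global
affine profile–profile alignment, scoring column pairs as fᵃᵀ·S·fᵇ with
gap mass dropped from the frequency vectors. It is an explicit stand-in
for MUSCLE/MAFFT-class aligners: no iterative refinement, O(nm) DP,
adequate at family scale (tens of sequences, ≤ ~500 columns); aligned
FASTA can be imported to substitute an external alignment. Motif-column
curation finds the `n_cols` = 2 columns with maximal Cys frequency
(ties → leftmost) and drops rows lacking Cys in either, automating the
usual visual inspection of a cysteine-motif alignment.

Conservation logos are reported as per-column information content,
IC = log₂20 − H with gaps excluded from counts and no pseudocounts (a
display statistic, not a model).

## Profile HMM

Standard match/insert/delete architecture. Match states are alignment
columns with gap fraction < 0.5; Laplace pseudocounts (1.0) on all
emission and transition counts; background uniform 1/20 by default
(database frequencies switchable). I→D and D→I transitions are not
modelled (textbook collapse). Scoring is glocal — global in the profile,
local in the sequence: flanking residues are emitted by free N/C states at
0 bits, so scores are log-odds bits for the best (Viterbi) or the sum
(forward) over alignments of the whole model within the sequence. X
residues score 0 (background). Both scoring modes are verified against
explicit path enumeration for small models.

E-values use a Gumbel null fitted by maximum likelihood
(scipy `gumbel_r.fit`) to Viterbi scores of n = 1000 random background
sequences with lengths uniform on [50, 400] (protein-scale); λ is the
inverse scale. E(s) = N·(1 − exp(−exp(−λ(s−μ)))) with N the database
size. Calibration is on Viterbi (not forward) scores for speed; fewer
than 100 samples are refused as unstable.

The iterative search mirrors jackhmmer: membership is defined by search
hits (iteration 1 re-finds the seeds), each iteration rebuilds the HMM
from the progressive re-alignment of all members, recalibrates with an
iteration-derived seed, and admits hits at E ≤ 0.01; the loop stops when
an iteration adds nothing (converged) or after `max_iter` = 11. After the
loop, members carrying any domain annotation at the E-ceiling are removed.
Membership is monotone non-decreasing before removal, and the whole
procedure is deterministic given (inputs, seed).

## Sequence similarity network

Sequences are collapsed by greedy single-linkage grouping at global
percent identity ≥ 90 %; the representative is the longest member (ties
lexicographic). Edges connect representatives with Smith–Waterman score
≥ 100. This raw-score threshold is a self-contained, monotone-equivalent
replacement for web-tool "alignment scores" (−log₁₀E-like); the two are
not numerically interchangeable, which matters only if thresholds are
copied between tools. Clusters are connected components with ids ordered
by smallest member; exemplar sequences label the cluster containing them,
with conflicts warned and kept.

## Co-occurrence statistics

All fractions are gene-level (per cluster gene or per family gene), with
windows at the discovery radius. Both the full-window and the
operon-restricted neighbor variants are emitted, clearly labelled, since
the "neighboring" statistic can be defined either way. Per-class rates
divide family counts by the number of proteomes per taxonomy class.
Counting is deterministic, so on generator output every fraction equals
the planted count ratio exactly.

## Phylogeny

Distances are Poisson-corrected p-distances over shared non-gap columns,
d = −ln(1−p), with p capped at 1−1e-9 for saturated pairs (a pair sharing
no columns is an error). Neighbor joining is the standard agglomeration
with negative branch lengths clamped to zero and the deficit moved to the
sister edge; ties resolve by smallest row-major index, the unrooted result
carries a trifurcating root. NJ is exact on additive matrices and is
oracle-checked for topology and path lengths. It is a deterministic
stand-in for approximate-ML inference; at desk scale the tree itself is
illustrative, not a reproduction of any published phylogeny.

Bootstrap supports resample columns with replacement (default 100
replicates; 1000 available), rebuild NJ per replicate, and score each
internal bipartition of the full-data tree by the fraction of replicates
containing it. Pruning collapses internal edges with support strictly
below the threshold (exactly 0.5 survives a 0.5 cutoff) into polytomies;
the collapsed edge's length is absorbed into its children's branches
(Bio.Phylo collapse semantics), leaves are never removed. Newick files
carry supports as internal node labels.

## Assay statistics

Specific activity converts an absorbance rate at 468 nm via Beer–Lambert
with ε = 14 800 M⁻¹ cm⁻¹: ((ΔA/min)/(ε·l))·V·10⁹/mg, in
nmol·min⁻¹·mg⁻¹. Cuvette path and reaction volume are explicit config
with no hidden defaults asserted as anyone's protocol. Relative activity
scales by the wild-type mean (set to 100 %), with the sample sd on the
same scale. The Welch t statistic with Satterthwaite degrees of freedom is
implemented directly (and cross-checked against scipy in tests); both
samples with zero variance and equal means give p = 1 by convention.
Significance stars (*, **, ***) threshold p at 0.05/0.01/0.001 with no
multiple-testing correction.

## Synthetic benchmark

The generator emulates the statistical structure the discovery procedure
assumes, at the default study scale of 30 genomes × 300 genes: 20
CutO-like, 3 CueO-like and 2 FtsP-like anchor genes (one per genome,
three cupredoxin-domain annotations each, members of three divergent
seed families at 15 % per-site divergence so the SSN separates them); a
40-member CutF-like family derived from a 118-residue seed (18-residue
signal block, central CXXHC, PP tail) at 30 % per-site divergence with
the signal/motif/tail positions protected; a CutG-like family; annotated
Cu-binding neighbor genes; 4 × 100 decoys (small motif-free proteins,
family mimics carrying a domain annotation, motif-bearing proteins
outside any window, > 170 aa motif proteins); and background genes
(60–350 aa, 60 % carrying a random domain annotation so the
no-known-domain rule does real work).

Planted co-occurrence rates (neighbor 0.40, genome 0.71, both-families
0.55, annotation 0.88, CueO/FtsP 0.08/0.02) are realized by exact counts,
round(p·n), not Bernoulli draws, so measured fractions have sharp expected
values; at n = 20 anchors the realized ratios are 8/20 = 40 %,
14/20 = 70 %, 11/20 = 55 %, 35/40 = 87.5 %. Substitutions are uniform
over the 19 alternatives with no rate matrix and no indels — family
discovery, not molecular evolution, is what the benchmark exercises.
Decoy signal peptides share the family's tripartite architecture but not
its residues: unrelated secreted proteins share signal structure, and a
byte-identical signal block would make a "decoy" a genuine homolog.
"Elsewhere" family members are spaced > 20 ranks apart so no family
window accidentally contains another member's planted annotation gene.

What passing these tests shows — and does not. The benchmark verifies
that the machinery is correct and that the procedure recovers a planted
family with the stated motif/signal/size structure under 30 % divergence
against motif-bearing decoys. Real proteomes add paralogy, indels,
annotation errors, compositional bias and release-dependent domain
definitions, none of which the generator models; published headline
counts from specific database releases are therefore out of reach by
construction, and the package makes no claim to reproduce them.

## Problem sizes and determinism

Default test and acceptance runs use the 30 × 300 benchmark (9 000
proteins), HMM calibration n = 1000, and 100 bootstrap replicates —
sizes chosen so a complete run finishes in tens of seconds on one CPU
while leaving every statistic at its planted value. All randomness flows
from a single integer seed through `numpy.random.default_rng`; repeated
runs are identical apart from wall-clock timings in the run log.
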