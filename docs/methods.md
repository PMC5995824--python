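# Methods

## Scope and data model

The toolkit describes one annotated, circular mitochondrial genome and
panels of them. A `Feature` is a named interval with 1-based inclusive
coordinates, a strand (J = majority/forward, N = minority/reverse; F/R
and +/− accepted on input) and a class (PCG, tRNA, rRNA,
control_region). Annotations are inputs: the package does no de-novo
gene finding, and start/stop codon classes are read from the annotated
codon strings only, never inferred from sequence context. The packaged
reference table transcribes the published annotation of the
*L. chinensis* mitogenome (GenBank MG252777); the published
intergenic-nucleotides column of that table is internally inconsistent
with its own coordinates and is deliberately not transcribed — all
spacer/overlap statistics are recomputed from coordinates, which yields
16 spacers (66 bp) and 6 overlaps (21 bp) rather than the prose totals.

Gap convention: for consecutive features sorted by start (ties: end
descending, then name), `gap = next.start − current.end − 1`; the
wrap-around pair closes the circle with
`first.start + genome_length − last.end − 1`. Max-overlap ties break to
the first pair in position order. The control region is a feature for
gap purposes but is excluded from the gene census.

## Composition and skew

Skews are (A−T)/(A+T) and (G−C)/(G+C); a zero denominator yields NaN
("undefined"), never 0. N bases are excluded from denominators and
counted separately. Region pools (PCGs, tRNAs, rRNAs) concatenate
features in genome order, each in coding orientation (N-strand features
reverse-complemented). Whether published per-region tables used the
coding or the majority strand for minority-strand genes is generally
unstated; coding orientation is the convention that reproduces
codon-position statistics, and `base_composition` can be applied to any
strand explicitly if the other convention is wanted. Codon-position
composition pools positions 1/2/3 across genes after dropping any
trailing incomplete codon. Reports round proportions to 1 decimal and
skews to 2, matching the conventional table layout; full precision is
kept internally and exposed with `--full-precision`.

## Codon analysis

Translation and synonymy are fixed to NCBI table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA/TAG).
The source organisms are Diptera, so table 5 is the only defensible
choice; it is a package constant, not a parameter. The ATCA quadruplet
start of COI is scored as its own class and, for downstream translation,
the reading frame begins after the quadruplet (annotated length
1540 = 4 + 511×3 + 3 keeps frame). RSCU counts sense codons of the
coding strand only, skipping each gene's first codon (start codons,
standard or not) and all stop or trailing incomplete codons; a
synonymous family with zero total is reported as absent (None/NaN)
rather than 0, so "codon never used in this species" is distinguishable
from "codon unused within a used family".

## Divergence

K2P: columns with a gap or non-ACGT symbol in either sequence are
excluded (pairwise deletion — the common default for published distance
tables; complete deletion would change values in the 3rd decimal at
most for data of this divergence). Purine↔purine and
pyrimidine↔pyrimidine mismatches are transitions. The distance is
`−½·ln((1−2P−Q)√(1−2Q))`; a non-positive log argument raises an explicit
saturation error rather than returning NaN.

Ka/Ks follows Nei & Gojobori (1986), the classic counting method behind
the software named in mitogenome papers. Per codon, each position
contributes a synonymous-site fraction equal to the share of synonymous
changes among the single-nucleotide changes that do not create a stop
codon, so S + N = 3 × codons exactly. Between differing codons, all
orderings of the differing positions are enumerated; pathways through
stop codons are discarded (all-blocked pairs fall back to the full set);
synonymous/nonsynonymous steps are averaged with equal weights. Sites
are averaged over the two sequences; pS = Sd/S and pN = Nd/N receive the
Jukes–Cantor correction `−¾·ln(1−4p/3)`, with an explicit error at
p ≥ 3/4. An independent implementation (biopython's NG86) agrees to a
few percent; the residual difference traces to stop-codon handling in
site counting.

## Phylogeny

Neighbor joining minimises the Q-criterion `(r−2)·d_ij − R_i − R_j`;
ties break to the lexicographically lowest pair of cluster
representatives (the smallest leaf label in each cluster), making output
deterministic on degenerate inputs. Negative branch-length estimates are
clamped to zero and logged. The final three clusters join by the
three-point formulas at an unrooted trifurcation. On additive matrices
this reconstruction is exact to machine precision, which is the
acceptance surface for topology claims: likelihood and Bayesian
inference are deliberately out of scope, so topological agreement — not
likelihoods or posteriors — is what the package tests.

Bootstrap resamples alignment columns with replacement; each replicate
uses the RNG stream `default_rng([seed, replicate_index])`, so runs are
reproducible and invariant to taxon input order (taxa are sorted
internally). Replicates with saturated distances are dropped and
counted; support = percentage of retained replicates containing each
bipartition of the full-data tree, and a warning is issued when more
than 5% are lost. Rooting places the root at the midpoint of the
outgroup's terminal branch and is idempotent.

## Control-region motifs

Homopolymer and (TA)n detectors report maximal runs; (TA)n is
phase-agnostic (an (AT)n run is the same motif) with copy number
run_length/2. The tandem-repeat scan tries every start and unit length
in range, extends while each additional copy matches the seed unit at
≥ the identity threshold, appends the exactly-matching prefix of a
partial final unit (fractional copy number), and resolves overlaps
greedily longest-span-first (ties: smaller unit, then lower start), so
reported hits never overlap or nest. Defaults — homopolymer min length
9, (TA)n min 5 copies, tandem unit ≤ 50 with min 2 copies at 85%
identity — were chosen once for a ~1.4 kb, 80–90% A+T insect control
region: long enough that chance hits in that background are rare
(verified by the Monte-Carlo null test), short enough to catch the
conserved elements. The published analysis states no thresholds; all of
these are exposed as CLI flags. This is a deliberately simple
periodicity scan, not a reimplementation of Tandem Repeats Finder's
probabilistic scoring model. No stem-loop prediction is attempted.

## Synthetic data: what it emulates, and what it does not

Generators return their ground truth alongside the data, and all are
bit-reproducible from `(parameters, seed)`; child streams use
`default_rng([seed, fixed_index])`.

- Annotation layouts tile the circle exactly from a planned list of
  feature lengths and signed gaps; the returned ledger contains the
  planned gap records and strand census.
- Sequence evolution uses the exact closed-form K2P substitution
  probabilities per branch (no discretised time steps), so the planted
  branch length is exactly the expected substitutions/site and distance
  recovery is unbiased.
- Codon pairs plant at most one single-step substitution per codon,
  synonymous with probability ks·s_i and nonsynonymous with ka·n_i
  (s_i/n_i the codon's NG86 site counts), so the planted pN and pS match
  the estimator's denominators by construction. The recovery study uses
  ks = 0.1, ka = 0.02 (ratio 0.2) over 5,000 codons.
- Tree datasets evolve a uniform-composition root sequence down a fixed
  7-taxon tree shaped like the published Agromyzidae phylogeny
  (((sativae,trifolii),(huidobrensis,bryoniae)),chinensis) with
  *C. horticola* and the *D. melanogaster* outgroup outside. Branch
  lengths were set once to reproduce the scale of the published K2P
  divergences (sativae–trifolii 0.085 up to ~0.21 for the most distant
  pair).
- Synthetic control regions embed planted motifs between AT-rich
  spacers that are actively scrubbed of chance repeats and separated by
  guard bases chosen not to extend the planted runs, so the ledger is
  the complete set of detectable hits at the test thresholds.

Passing these tests shows the estimators invert their own generating
models at realistic sizes. Real mitogenomes violate those models in
known ways the generators do not emulate: among-site rate variation and
base-composition bias (K2P assumes homogeneity), codon-usage and
selection heterogeneity along genes, indels and alignment error
(alignments here are gap-free by construction), and within-genome
composition gradients. Agreement with published values on real data is
therefore checked separately, against the deposited sequences where
available.

## Problem sizes

Recovery studies run at the sizes the guarantees are stated for:
100 kb pairs for single-distance recovery, 5,000 codons × 100 seeds for
Ka/Ks, 20 kb × 100 seeds for clade recovery, 1000 bootstrap replicates
for support values. These sizes give standard errors comfortably inside
the asserted bands while keeping the whole battery at around ten
seconds.

## Known limitations

- No alignment algorithm: codon alignments are inputs (or generated
  gap-free); misalignment effects are untested.
- Ka/Ks is NG86 with equal pathway weights; no transition/transversion
  weighting (Li-style) or maximum-likelihood (Goldman–Yang) estimators.
- NJ + bootstrap only; no likelihood models, model selection, or MCMC.
- The GenBank reader takes codon annotations only from explicit note
  qualifiers; records lacking them classify as unannotated rather than
  guessing from sequence.
- Sequence-level checks against the deposited accessions require the
  user to supply those sequences (see tests/data/accessions/README.txt).
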