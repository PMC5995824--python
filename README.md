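# mitocomp

A toolkit for the comparative analysis of annotated animal mitochondrial
genomes, built around the workflow used to characterise newly sequenced
insect mitogenomes: annotation-table accounting, nucleotide composition
and strand skew, codon usage, pairwise divergence, distance-based
phylogeny, and control-region motif detection. It ships the published
annotation table of the *Liriomyza chinensis* (onion leafminer)
mitogenome, GenBank MG252777, as a reference dataset, and a
synthetic-data module that generates every input with known ground
truth so the whole pipeline is testable offline.

It is aimed at people who assemble and annotate mitogenomes and want the
standard descriptive battery — the numbers that go into the annotation
table, composition tables, codon-usage figure, divergence matrix and
phylogeny figure of a mitogenome paper — reproducibly, from the shell or
from Python.

## What it computes

**Annotation accounting.** Features live on a circular molecule with
1-based inclusive coordinates. For consecutive features in position
order (including the wrap-around pair) the signed intergenic distance is
`gap = next.start − current.end − 1`; positive values are spacers,
negative values overlaps. Strand census counts genes per majority (J)
and minority (N) strand and per class (PCG / tRNA / rRNA).

**Composition and skew.** AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C),
computed whole-genome, per region class and per codon position (genes
taken in coding orientation).

**Codon analysis.** Translation and synonymy under NCBI table 5
(invertebrate mitochondrial). Start/stop classification covers the
nonstandard dipteran forms: GTG and TTG starts, the ATCA quadruplet
start, and incomplete stops `T`/`TA` completed by polyadenylation.
RSCU of codon *c* in a synonymous family of size *k* with total *n* is
`count_c · k / n`; an entirely unused family is reported as absent, not 0.

**Divergence.** Kimura 2-parameter distance
`d = −½·ln((1−2P−Q)·√(1−2Q))` from transition (P) and transversion (Q)
proportions with pairwise deletion of gap/ambiguous columns; and
Nei–Gojobori (1986) Ka/Ks: per-codon synonymous/nonsynonymous site
fractions, equal-weight averaging over all minimal substitution
pathways, Jukes–Cantor correction `K = −¾·ln(1−4p/3)`.

**Phylogeny.** Neighbor joining on K2P distances (exact on additive
matrices), nonparametric bootstrap by column resampling, outgroup
rooting, Newick output with supports as internal node labels.

**Control region.** Maximal poly-T/poly-A runs, phase-agnostic (TA)n
runs, and an exhaustive small-unit tandem-repeat scan with a per-unit
identity threshold.

## Worked example

Accounting on the packaged reference annotation (the path is the
packaged TSV, available via
`python -c "from importlib import resources; print(resources.files('mitocomp.data')/'liriomyza_chinensis_mg252777.tsv')"`):

```
$ mitocomp annotate-stats <path-to>/liriomyza_chinensis_mg252777.tsv
genome_length   16175
features        38
spacers         16      total 66 bp     longest 19 bp ('trnE', 'trnF')
overlaps        6       total 21 bp     longest 8 bp ('trnW', 'trnC')
strand_J        23      PCG 9, tRNA 14, rRNA 0
strand_N        14      PCG 4, tRNA 8, rRNA 2
```

The 16,175 bp circle carries 16 intergenic spacers (66 bp in total, the
longest 19 bp between trnE and trnF), 6 gene overlaps (longest 8 bp,
trnW/trnC), and 23 of the 37 genes on the majority strand. Start/stop
codon classes of the 13 protein-coding genes:

```
$ mitocomp codons <path-to>/liriomyza_chinensis_mg252777.tsv
start_classes   ATCA:1, ATN:11, GTG:1
stop_classes    T:4, TA:1, TAA:7, TAG:1
incomplete_stops        CYTB, ND2, ND4, ND4L, ND5
```

Eleven genes start with ATN; COI uses the ATCA quadruplet and ND1 uses
GTG; five genes end in incomplete stops. A synthetic 7-taxon dataset and
its NJ + bootstrap tree:

```
$ mitocomp simulate --seed 7 --taxa-seq-len 8000 -o synth
$ mitocomp tree synth/synthetic_alignment.fasta --bootstrap 200 --seed 1 \
      --outgroup D_melanogaster
(D_melanogaster:0.0875,(C_horticola:0.1029,(((L_bryoniae:0.0479,L_huidobrensis:0.0508)100:0.0300,(L_sativae:0.0462,L_trifolii:0.0432)100:0.0306)100:0.0215,L_chinensis:0.0902):0.0210)100:0.0875);
```

(branch lengths abbreviated here; the tool prints full precision). The
internal-node labels are bootstrap percentages: both sibling-species
clades and the ingroup are recovered with 100% support, with the
outgroup basal — the topology the data were generated under.

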