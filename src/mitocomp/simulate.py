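"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be produced here with the
true answer returned alongside the data: annotation tables with a planned
spacer/overlap layout, sequences with controlled base composition,
sequence pairs diverged under the K2P model at a known distance, codon
alignments with planted synonymous/nonsynonymous substitution rates, and
multi-taxon datasets evolved down a known tree.

All generators are bit-reproducible from their integer seed.  Child RNG
streams are derived as ``numpy.random.default_rng([seed, index])`` with
fixed, documented indices.  K2P evolution uses the exact closed-form
substitution probabilities of the model (no discretised time steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import dendropy
import numpy as np

from .codons import CODON_TO_AA, STOP_CODONS, SENSE_CODONS
from .control_region import MotifHit
from .divergence import _codon_sites
from .genome import AnnotationTable, Feature, GapRecord, Mitogenome, strand_census

_BASES = np.array(list("ACGT"))
_IDX = {b: i for i, b in enumerate("ACGT")}

#: unrooted 7-taxon tree shaped like the published Agromyzidae phylogeny,
#: with branch lengths (subs/site) chosen to reproduce the scale of the
#: observed K2P divergences (sativae-trifolii 0.085 ... horticola ~0.2)
AGROMYZID_TREE_NEWICK = (
    "((((L_sativae:0.042,L_trifolii:0.043):0.030,"
    "(L_huidobrensis:0.047,L_bryoniae:0.049):0.030):0.018,"
    "L_chinensis:0.095):0.020,C_horticola:0.100,D_melanogaster:0.180);"
)


# ---------------------------------------------------------------------------
# Annotation-table generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorSpec:
    """Plan for one synthetic annotated genome.

    ``layout`` lists (name, feature_class, strand, length) in circle order;
    ``gaps`` gives the signed gap AFTER each feature (last entry = the
    wrap-around gap back to the first feature).  Feature lengths plus gaps
    must tile the circle exactly: sum(lengths) + sum(gaps) == genome_length.
    """

    seed: int
    genome_length: int
    layout: list[tuple[str, str, str, int]]
    gaps: list[int]
    base_probs: tuple[float, float, float, float] = (0.39, 0.13, 0.10, 0.38)  # ACGT

    def __post_init__(self) -> None:
        if len(self.layout) != len(self.gaps):
            raise ValueError("need one gap per feature (last = wrap gap)")


def make_annotation_table(spec: GeneratorSpec) -> tuple[AnnotationTable, dict]:
    """Build an AnnotationTable from a layout plan, plus its ground truth.

    Returns (table, ledger); the ledger holds the planned GapRecords and
    the strand census so downstream tests never re-derive the truth.
    """
    if not spec.layout:
        raise ValueError("empty layout plan")
    total = sum(length for *_, length in spec.layout) + sum(spec.gaps)
    if total != spec.genome_length:
        raise ValueError(
            f"layout does not tile the circle: lengths+gaps={total}, "
            f"genome_length={spec.genome_length}"
        )
    features = []
    ledger_gaps = []
    pos = 1
    for (name, fclass, strand, length), gap in zip(spec.layout, spec.gaps):
        start = pos
        end = start + length - 1
        if start < 1 or end > spec.genome_length:
            raise ValueError(f"{name}: feature {start}..{end} leaves the circle")
        features.append(Feature(name=name, start=start, end=end, strand=strand,
                                feature_class=fclass))
        pos = end + gap + 1
    for (up, _, _, _), (down, _, _, _), gap in zip(
            spec.layout, spec.layout[1:] + spec.layout[:1], spec.gaps):
        ledger_gaps.append(GapRecord(up, down, gap))
    table = AnnotationTable(genome_length=spec.genome_length, features=features)
    ledger = {"gaps": ledger_gaps, "census": strand_census(table)}
    return table, ledger


def random_layout_spec(seed: int, n_features: int = 12,
                       mean_gene_len: int = 300) -> GeneratorSpec:
    """A random feasible layout plan (for property tests)."""
    rng = np.random.default_rng([seed, 0])
    classes = ["PCG", "tRNA", "rRNA"]
    layout = []
    gaps = []
    for i in range(n_features):
        fclass = classes[int(rng.integers(0, 3))]
        length = int(rng.integers(60, 2 * mean_gene_len))
        strand = "J" if rng.random() < 0.6 else "N"
        layout.append((f"g{i + 1}_{fclass}", fclass, strand, length))
        gaps.append(int(rng.integers(0, 25)))
    genome_length = sum(l for *_, l in layout) + sum(gaps)
    return GeneratorSpec(seed=seed, genome_length=genome_length,
                         layout=layout, gaps=gaps)


# ---------------------------------------------------------------------------
# Sequences with controlled composition
# ---------------------------------------------------------------------------

def random_sequence(length: int, seed: int = 0,
                    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    """Random i.i.d. nucleotide string with base probabilities (A, C, G, T)."""
    rng = np.random.default_rng([seed, 1])
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("base_probs must be 4 probabilities summing to 1")
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def make_genome(spec: GeneratorSpec) -> tuple[Mitogenome, dict]:
    """Synthetic genome: layout from the plan, sequence from base_probs."""
    table, ledger = make_annotation_table(spec)
    seq = random_sequence(spec.genome_length, seed=spec.seed,
                          base_probs=spec.base_probs)
    return Mitogenome(table=table, sequence=seq,
                      accession=f"SYN{spec.seed}"), ledger


def coding_sequence_with_pos3_at(n_codons: int, pos3_at: float, seed: int = 0) -> str:
    """In-frame coding sequence whose 3rd codon position has an exact
    expected A+T proportion; stop codons are avoided without disturbing
    the position-3 distribution (positions 1-2 are resampled instead)."""
    rng = np.random.default_rng([seed, 2])
    codons = []
    for _ in range(n_codons):
        if rng.random() < pos3_at:
            p3 = "A" if rng.random() < 0.5 else "T"
        else:
            p3 = "C" if rng.random() < 0.5 else "G"
        while True:
            p1, p2 = _BASES[rng.integers(0, 4, size=2)]
            if p1 + p2 + p3 not in STOP_CODONS:
                break
        codons.append(p1 + p2 + p3)
    return "".join(codons)


# ---------------------------------------------------------------------------
# K2P evolution
# ---------------------------------------------------------------------------

def _k2p_probs(distance: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_transversion_total) after a branch of the
    given expected length under K2P with ts/tv rate ratio kappa."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    alpha_t = distance * kappa / (kappa + 2.0)
    beta_t = distance / (kappa + 2.0)
    e1 = math.exp(-4.0 * beta_t)
    e2 = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return 1.0 - p_ts - p_tv, p_ts, p_tv


def evolve_k2p(ancestor: str, distance: float, kappa: float = 2.0,
               seed: Union[int, np.random.Generator] = 0) -> str:
    """Evolve a sequence along one branch under the K2P model.

    Each site substitutes according to the exact K2P transition
    probabilities at the given branch length (expected substitutions/site),
    so the estimated K2P distance to the ancestor is unbiased.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng([seed, 3])
    p_same, p_ts, p_tv = _k2p_probs(distance, kappa)
    enc = np.array([_IDX[b] for b in ancestor.upper()], dtype=np.uint8)
    u = rng.random(len(enc))
    out = enc.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    out[ts_mask] ^= 2  # A<->G (0<->2), C<->T (1<->3)
    tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv / 2.0)
    tv2 = u >= p_same + p_ts + p_tv / 2.0
    out[tv1] ^= 1  # A<->C, G<->T
    out[tv2] ^= 3  # A<->T, C<->G
    return "".join(_BASES[out])


# ---------------------------------------------------------------------------
# Codon-pair simulation with planted Ka/Ks
# ---------------------------------------------------------------------------

def _single_step_neighbors(codon: str) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous) single-nucleotide neighbours, stops excluded."""
    syn, nonsyn = [], []
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            (syn if CODON_TO_AA[mut] == aa else nonsyn).append(mut)
    return syn, nonsyn


def simulate_codon_pair(codons: int, ks_true: float, ka_true: float,
                        seed: int = 0) -> tuple[str, str]:
    """Codon alignment pair with substitutions planted at known rates.

    Sequence A is a random ancestor of sense codons; sequence B plants a
    synonymous change with probability ks_true * s_i and a nonsynonymous
    change with probability ka_true * n_i per codon (s_i/n_i = the codon's
    NG86 site counts), so the Nei-Gojobori estimate recovers Ka/Ks =
    ka_true/ks_true up to sampling noise.  At most one substitution per
    codon; rates must stay far from saturation.
    """
    if codons < 1:
        raise ValueError("need at least one codon")
    if ks_true < 0 or ka_true < 0:
        raise ValueError("rates must be >= 0")
    if 3.0 * max(ks_true, ka_true) > 0.5:
        raise ValueError("requested rates are too close to saturation")
    rng = np.random.default_rng([seed, 4])
    a_codons = []
    b_codons = []
    for _ in range(codons):
        codon = SENSE_CODONS[int(rng.integers(0, len(SENSE_CODONS)))]
        a_codons.append(codon)
        s_i, n_i = _codon_sites(codon)
        syn, nonsyn = _single_step_neighbors(codon)
        p_syn = ks_true * s_i if syn else 0.0
        p_nonsyn = ka_true * n_i if nonsyn else 0.0
        u = rng.random()
        if u < p_syn:
            b_codons.append(syn[int(rng.integers(0, len(syn)))])
        elif u < p_syn + p_nonsyn:
            b_codons.append(nonsyn[int(rng.integers(0, len(nonsyn)))])
        else:
            b_codons.append(codon)
    return "".join(a_codons), "".join(b_codons)


# ---------------------------------------------------------------------------
# Tree-structured datasets
# ---------------------------------------------------------------------------

def make_tree_dataset(tree: Union[str, dendropy.Tree], root_seq_len: int,
                      seed: int = 0, kappa: float = 2.0,
                      base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                      ) -> dict[str, str]:
    """Evolve sequences down a tree; returns {taxon label: sequence}.

    The root sequence is i.i.d. with ``base_probs``; each edge applies
    :func:`evolve_k2p` at its branch length.  Edge RNG streams are seeded
    by the node's deterministic preorder index, so the dataset is
    reproducible from (tree, seed) alone.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    root_seq = random_sequence(root_seq_len, seed=seed, base_probs=base_probs)
    seqs: dict[str, str] = {}
    node_seq = {tree.seed_node: root_seq}
    for index, node in enumerate(tree.preorder_node_iter()):
        if node is tree.seed_node:
            continue
        parent_seq = node_seq[node.parent_node]
        bl = node.edge.length or 0.0
        rng = np.random.default_rng([seed, 5, index])
        node_seq[node] = evolve_k2p(parent_seq, bl, kappa=kappa, seed=rng)
    for leaf in tree.leaf_node_iter():
        seqs[leaf.taxon.label] = node_seq[leaf]
    if not seqs:  # single-node tree degenerates to the root sequence
        label = tree.seed_node.taxon.label if tree.seed_node.taxon else "root"
        seqs[label] = root_seq
    return seqs


# ---------------------------------------------------------------------------
# Control-region builder with planted motifs
# ---------------------------------------------------------------------------

@dataclass
class MotifPlant:
    """One motif to embed: class poly_T/poly_A needs length; TA_repeat
    needs copies; tandem_repeat needs unit and copies."""

    motif_class: str
    length: int = 0
    copies: int = 0
    unit: str = ""

    def render(self) -> str:
        if self.motif_class == "poly_T":
            return "T" * self.length
        if self.motif_class == "poly_A":
            return "A" * self.length
        if self.motif_class == "TA_repeat":
            return "TA" * self.copies
        if self.motif_class == "tandem_repeat":
            return self.unit * self.copies
        raise ValueError(f"unknown motif class {self.motif_class!r}")


def _quiet_background(length: int, rng: np.random.Generator) -> str:
    """AT-rich background verified repeat-free, so planted motifs are the
    only detectable hits: any chance homopolymer run (>= 6) or perfect
    small-unit tandem (>= 3 copies, unit <= 10) is mutated away."""
    from .control_region import find_homopolymers, find_tandem_repeats

    seq = list(_BASES[rng.choice(4, size=length, p=[0.35, 0.15, 0.15, 0.35])])
    for _ in range(50):
        s = "".join(seq)
        hits = [h for base in "ACGT"
                for h in find_homopolymers(s, base, min_len=6)]
        hits += find_tandem_repeats(s, max_unit=10, min_copies=3,
                                    min_identity=1.0, min_unit=2)
        if not hits:
            return s
        for h in hits:
            mid = (h.start + h.end) // 2 - 1
            options = [b for b in "ACGT" if b != seq[mid]]
            seq[mid] = options[int(rng.integers(0, 3))]
    raise RuntimeError("could not generate a repeat-free background")


def make_control_region(seed: int, plants: Sequence[MotifPlant],
                        spacer_len: int = 60) -> tuple[str, list[MotifHit]]:
    """Synthetic control region with planted motifs and a ground-truth ledger.

    Motifs are separated by quiet AT-rich spacers and flanked by G/C guard
    bases so each planted run is maximal exactly as planted.
    """
    rng = np.random.default_rng([seed, 6])
    parts = [_quiet_background(spacer_len, rng)]
    ledger: list[MotifHit] = []
    pos = spacer_len
    for plant in plants:
        motif = plant.render()
        # guards must not extend the planted run (same-phase or rotated)
        if plant.motif_class == "tandem_repeat":
            guard_l = next(b for b in "CGTA" if b != motif[-1])
            guard_r = next(b for b in "GCAT" if b != motif[0])
        else:
            guard_l, guard_r = "G", "C"
        parts.append(guard_l)
        pos += len(guard_l)
        start = pos + 1
        parts.append(motif)
        pos += len(motif)
        unit = {"poly_T": "T", "poly_A": "A", "TA_repeat": "TA"}.get(
            plant.motif_class, plant.unit)
        copies = len(motif) / len(unit)
        ledger.append(MotifHit(plant.motif_class, start, pos, unit, copies))
        parts.append(guard_r)
        pos += len(guard_r)
        parts.append(_quiet_background(spacer_len, rng))
        pos += spacer_len
    seq = _scrub_junction_repeats("".join(parts), ledger, rng)
    return seq, ledger


def _scrub_junction_repeats(seq: str, ledger: Sequence[MotifHit],
                            rng: np.random.Generator) -> str:
    """Remove chance repeats created where spacers meet guards, mutating
    only positions outside the planted spans."""
    from .control_region import find_homopolymers, find_tandem_repeats

    chars = list(seq)
    planted = [(h.start, h.end) for h in ledger]

    def _outside(i: int) -> bool:  # 0-based index
        return all(not (s - 1 <= i <= e - 1) for s, e in planted)

    for _ in range(50):
        s = "".join(chars)
        hits = [h for base in "ACGT"
                for h in find_homopolymers(s, base, min_len=6)]
        hits += find_tandem_repeats(s, max_unit=10, min_copies=3,
                                    min_identity=1.0, min_unit=2)
        stray = [h for h in hits
                 if not any(ps <= h.start and h.end <= pe for ps, pe in planted)]
        if not stray:
            return s
        for h in stray:
            targets = [i for i in range(h.start - 1, h.end) if _outside(i)]
            if not targets:
                continue
            i = targets[len(targets) // 2]
            left = chars[i - 1] if i > 0 else ""
            right = chars[i + 1] if i + 1 < len(chars) else ""
            options = [b for b in "GCAT"
                       if b != chars[i] and b != left and b != right]
            chars[i] = options[int(rng.integers(0, len(options)))]
    raise RuntimeError("could not scrub junction repeats")
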