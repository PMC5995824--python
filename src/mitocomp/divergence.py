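"""Pairwise sequence divergence: K2P distances and Nei-Gojobori Ka/Ks.

The Kimura 2-parameter distance separates the observed proportions of
transitions (P) and transversions (Q) over compared sites and corrects
for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Ka and Ks follow the pathway-counting method of Nei & Gojobori (1986)
under the invertebrate mitochondrial code: per-codon synonymous and
nonsynonymous site fractions, all minimal substitution pathways between
differing codons averaged with equal weights (pathways through stop
codons excluded), and a Jukes-Cantor correction

    K = -3/4 * ln(1 - 4p/3)

applied to the proportions pS = Sd/S and pN = Nd/N.  Columns containing
gaps or ambiguous bases in either sequence are excluded pairwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import CODON_TO_AA, STOP_CODONS, iter_codons


class SaturationError(ValueError):
    """Distance correction undefined: sequences too diverged."""


# ---------------------------------------------------------------------------
# Site-pattern counting and K2P
# ---------------------------------------------------------------------------

#: nucleotide byte encoding; purines map to even codes, pyrimidines to odd,
#: so a mismatch is a transition iff the parities agree
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = (0, 1, 2, 3)[_i]
    _ENC[ord(_b.lower())] = (0, 1, 2, 3)[_i]
del _i, _b


def encode_sequence(seq: str) -> np.ndarray:
    """Byte-encode a nucleotide string (A=0 C=1 G=2 T=3, other=255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Compared sites and transition/transversion tallies for one pair."""

    sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.sites

    @property
    def Q(self) -> float:
        return self.transversions / self.sites

    @property
    def p_distance(self) -> float:
        return (self.transitions + self.transversions) / self.sites


def count_site_patterns(a: str, b: str) -> PairwiseSiteCounts:
    """Classify aligned columns into identities/transitions/transversions.

    Columns with a gap or ambiguous base in either sequence are excluded
    (pairwise deletion).  Purine<->purine and pyrimidine<->pyrimidine
    mismatches are transitions; all other mismatches transversions.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    ea, eb = encode_sequence(a), encode_sequence(b)
    valid = (ea < 4) & (eb < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    diff = valid & (ea != eb)
    ts = int((diff & ((ea & 1) == (eb & 1))).sum())
    tv = int(diff.sum()) - ts
    return PairwiseSiteCounts(sites=n, transitions=ts, transversions=tv)


def k2p_distance(counts: PairwiseSiteCounts) -> float:
    """Kimura 2-parameter distance in substitutions/site."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined at P={P:.4f}, Q={Q:.4f}: sequences saturated"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_pairwise(a: str, b: str) -> float:
    return k2p_distance(count_site_patterns(a, b))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon.

    At each position the fraction of single-nucleotide changes that are
    synonymous is computed over the changes that do not create a stop
    codon; each position contributes 1 site in total.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        possible = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            possible += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if possible:
            s += syn / possible
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between
    two sense codons.  All orderings of the differing positions are
    enumerated; pathways through stop codons are discarded (unless every
    pathway is blocked, in which case all are used)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for frm, to in steps:
            if CODON_TO_AA.get(frm) == CODON_TO_AA.get(to):
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a proportion of differences."""
    if p >= 0.75:
        raise SaturationError(f"Jukes-Cantor correction undefined for p={p:.4f}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsCounts:
    """Nei-Gojobori site/difference counts and corrected rates."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def pS(self) -> float:
        return self.syn_diffs / self.syn_sites

    @property
    def pN(self) -> float:
        return self.nonsyn_diffs / self.nonsyn_sites

    @property
    def Ks(self) -> float:
        return jukes_cantor(self.pS)

    @property
    def Ka(self) -> float:
        return jukes_cantor(self.pN)

    @property
    def ka_ks(self) -> float:
        ks = self.Ks
        if ks == 0.0:
            return math.nan
        return self.Ka / ks


def nei_gojobori(a: str, b: str) -> KaKsCounts:
    """NG86 Ka/Ks counts for a pair of aligned in-frame coding sequences.

    Codon columns containing gaps or ambiguous bases in either sequence
    are excluded pairwise; a stop codon inside the alignment is an error
    (strip terminal stops first).
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    codons_a, codons_b = iter_codons(a), iter_codons(b)
    S = N = Sd = Nd = 0.0
    compared = 0
    for idx, (ca, cb) in enumerate(zip(codons_a, codons_b), start=1):
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon at codon {idx} ({ca}/{cb}); "
                             "strip terminal stop codons before Ka/Ks")
        if ca not in CODON_TO_AA or cb not in CODON_TO_AA:
            continue  # gap or ambiguity: pairwise deletion
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pair_differences(ca, cb)
        Sd += sd
        Nd += nd
        compared += 1
    if compared == 0:
        raise ValueError("no comparable codons after pairwise deletion")
    return KaKsCounts(syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named taxa."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def k2p_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """All-pairs K2P distances over an aligned set of taxa."""
    labels = list(alignment)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = k2p_pairwise(alignment[labels[i]], alignment[labels[j]])
        except SaturationError as exc:
            raise SaturationError(f"{labels[i]} vs {labels[j]}: {exc}") from None
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, values=mat)


def k2p_matrix_from_encoded(labels: Sequence[str], encoded: np.ndarray) -> DistanceMatrix:
    """K2P matrix from a pre-encoded (taxa x columns) byte matrix.

    Vectorised path used by the bootstrap, equivalent to
    :func:`k2p_matrix` on the decoded strings.
    """
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ea, eb = encoded[i], encoded[j]
        valid = (ea < 4) & (eb < 4)
        sites = int(valid.sum())
        if sites == 0:
            raise ValueError(f"{labels[i]} vs {labels[j]}: no comparable sites")
        diff = valid & (ea != eb)
        ts = int((diff & ((ea & 1) == (eb & 1))).sum())
        tv = int(diff.sum()) - ts
        d = k2p_distance(PairwiseSiteCounts(sites, ts, tv))
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=list(labels), values=mat)


def divergence_matrix(alignment: Mapping[str, str], method: str = "K2P") -> DistanceMatrix:
    """All-pairs divergence matrix: method "K2P", "Ka" or "Ks".

    Ka/Ks modes require an in-frame codon alignment.
    """
    if method == "K2P":
        return k2p_matrix(alignment)
    if method not in ("Ka", "Ks"):
        raise ValueError(f"unknown method {method!r}")
    labels = list(alignment)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        counts = nei_gojobori(alignment[labels[i]], alignment[labels[j]])
        mat[i, j] = mat[j, i] = counts.Ka if method == "Ka" else counts.Ks
    return DistanceMatrix(labels=labels, values=mat)


def kaks_vs_reference(alignment: Mapping[str, str], reference: str) -> pd.DataFrame:
    """Ka, Ks and Ka/Ks of every taxon against one reference taxon."""
    if reference not in alignment:
        raise KeyError(f"reference taxon {reference!r} not in alignment")
    rows = []
    for name, seq in alignment.items():
        if name == reference:
            continue
        c = nei_gojobori(seq, alignment[reference])
        rows.append({"taxon": name, "Ka": c.Ka, "Ks": c.Ks, "Ka/Ks": c.ka_ks})
    return pd.DataFrame(rows).set_index("taxon")


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    dm.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")
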