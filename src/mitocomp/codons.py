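"""Codon-level analysis under the invertebrate mitochondrial genetic code.

All translation and synonymy in this package uses NCBI translation table 5
(invertebrate mitochondrial: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops are
TAA/TAG only).  Provides translation, start/stop codon classification —
including the nonstandard forms seen in dipteran mitogenomes (GTG and TTG
starts, the ATCA quadruplet start, incomplete stops "T" and "TA" completed
by mRNA polyadenylation) — codon counting, and relative synonymous codon
usage (RSCU).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

MITO_TABLE_ID = 5
_TABLE5 = unambiguous_dna_by_id[MITO_TABLE_ID]

#: codon -> amino acid (one-letter), sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE5.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE5.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> synonymous codon family (sorted tuples)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in sorted(set(CODON_TO_AA.values()))
}

START_CLASSES = ("ATN", "GTG", "TTG", "ATCA", "other")
STOP_CLASSES = ("TAA", "TAG", "TA", "T", "other")


def split_codon_positions(seq: str) -> tuple[str, str, str]:
    """Split an in-frame coding sequence into its three codon-position
    strings; a trailing incomplete codon (1-2 nt) is dropped.
    """
    s = seq.upper()
    n_full = len(s) // 3
    if n_full == 0:
        raise ValueError(f"sequence of length {len(s)} has no complete codon")
    s = s[: n_full * 3]
    return s[0::3], s[1::3], s[2::3]


def iter_codons(seq: str) -> list[str]:
    """Complete codons of an in-frame sequence (trailing 1-2 nt dropped)."""
    s = seq.upper()
    return [s[i:i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def translate_mito(seq: str) -> str:
    """Translate an in-frame coding sequence under table 5.

    Codons containing N (or any non-ACGT symbol) yield "X"; internal stop
    codons yield "*"; a trailing incomplete codon is skipped.
    """
    out = []
    for codon in iter_codons(seq):
        if codon in CODON_TO_AA:
            out.append(CODON_TO_AA[codon])
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


@dataclass(frozen=True)
class CodonClassification:
    """Start/stop codon classes of one protein-coding gene, read from the
    annotated codon strings only (never inferred from sequence context)."""

    gene: str
    start_codon: Optional[str]
    stop_codon: Optional[str]

    @property
    def start_class(self) -> str:
        c = (self.start_codon or "").upper()
        if c == "ATCA":
            return "ATCA"
        if len(c) == 3 and c.startswith("AT"):
            return "ATN"
        if c in ("GTG", "TTG"):
            return c
        return "other"

    @property
    def stop_class(self) -> str:
        c = (self.stop_codon or "").upper()
        if c in ("TAA", "TAG", "TA", "T"):
            return c
        return "other"

    @property
    def incomplete_stop(self) -> bool:
        return self.stop_class in ("TA", "T")


def classify_codons(table) -> tuple[list[CodonClassification], dict]:
    """Classify start/stop codons of every annotated PCG.

    PCGs lacking codon annotations are excluded from the summary with a
    warning.  Returns (classifications, summary) where summary holds
    per-class Counters plus exact start-codon tallies.
    """
    rows = []
    for feat in table.by_class("PCG"):
        if feat.start_codon is None and feat.stop_codon is None:
            warnings.warn(
                f"{feat.name}: PCG without codon annotation, excluded from counts",
                stacklevel=2,
            )
            continue
        rows.append(CodonClassification(feat.name, feat.start_codon, feat.stop_codon))
    summary = {
        "start_classes": Counter(r.start_class for r in rows),
        "stop_classes": Counter(r.stop_class for r in rows),
        "start_codons": Counter((r.start_codon or "?").upper() for r in rows),
        "incomplete_stops": sorted(r.gene for r in rows if r.incomplete_stop),
    }
    return rows, summary


def codon_usage(seqs: Sequence[str], skip_start: bool = True) -> Counter:
    """Count sense codons across in-frame coding sequences.

    With ``skip_start`` the first codon of each gene is dropped (start
    codons, standard or not, are not part of usage); stop codons and
    trailing incomplete codons are never counted.
    """
    counts: Counter = Counter()
    for seq in seqs:
        codons = iter_codons(seq)
        if skip_start and codons:
            codons = codons[1:]
        for c in codons:
            if c in CODON_TO_AA:
                counts[c] += 1
    return counts


def rscu(usage_counts: Mapping[str, int]) -> dict[str, Optional[float]]:
    """Relative synonymous codon usage per sense codon.

    For codon c in a synonymous family of size k with family total n:
    RSCU = count_c * k / n (count divided by the family mean).  Families
    with zero total yield None ("absent", distinct from an RSCU of 0 for
    an unused codon in a used family).  Stop codons are excluded.
    """
    values: dict[str, Optional[float]] = {}
    for family in SYNONYMOUS_FAMILIES.values():
        total = sum(usage_counts.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                values[c] = None
        else:
            mean = total / len(family)
            for c in family:
                values[c] = usage_counts.get(c, 0) / mean
    return values


def rscu_table(per_species_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Codon x species RSCU matrix (absent families as NaN), with the
    encoded amino acid as a leading column."""
    data = {}
    for species, counts in per_species_counts.items():
        vals = rscu(counts)
        data[species] = {c: (math.nan if vals[c] is None else vals[c])
                         for c in SENSE_CODONS}
    df = pd.DataFrame(data, index=list(SENSE_CODONS))
    df.insert(0, "aa", [CODON_TO_AA[c] for c in df.index])
    return df
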