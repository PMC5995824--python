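"""Base composition, A+T content and strand-skew statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) measure the
asymmetry of base usage between the two strands of a mitochondrial
genome; insect mitogenomes typically show positive AT-skew and negative
GC-skew on the majority strand.  Proportions are computed over non-N
bases; reports round proportions to 1 decimal and skews to 2 decimals,
full precision is kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .codons import split_codon_positions
from .genome import Mitogenome, extract_region


@dataclass(frozen=True)
class CompositionSummary:
    """Counts and percentages of A/C/G/T with AT/GC skews for one region."""

    n_A: int
    n_T: int
    n_G: int
    n_C: int
    n_N: int = 0

    @property
    def total(self) -> int:
        """Non-N bases."""
        return self.n_A + self.n_T + self.n_G + self.n_C

    @property
    def pA(self) -> float:
        return 100.0 * self.n_A / self.total

    @property
    def pT(self) -> float:
        return 100.0 * self.n_T / self.total

    @property
    def pG(self) -> float:
        return 100.0 * self.n_G / self.total

    @property
    def pC(self) -> float:
        return 100.0 * self.n_C / self.total

    @property
    def at_content(self) -> float:
        return self.pA + self.pT

    @property
    def gc_content(self) -> float:
        return self.pG + self.pC

    @property
    def at_skew(self) -> float:
        return skew(self.n_A, self.n_T)

    @property
    def gc_skew(self) -> float:
        return skew(self.n_G, self.n_C)

    def __add__(self, other: "CompositionSummary") -> "CompositionSummary":
        return CompositionSummary(
            self.n_A + other.n_A, self.n_T + other.n_T,
            self.n_G + other.n_G, self.n_C + other.n_C,
            self.n_N + other.n_N,
        )

    def as_row(self) -> dict:
        """Report row with the conventional rounding (1 dp / 2 dp)."""
        return {
            "A": round(self.pA, 1), "T": round(self.pT, 1),
            "G": round(self.pG, 1), "C": round(self.pC, 1),
            "A+T": round(self.at_content, 1), "G+C": round(self.gc_content, 1),
            "AT-skew": round(self.at_skew, 2), "GC-skew": round(self.gc_skew, 2),
        }


def skew(x_count: float, y_count: float) -> float:
    """(x - y)/(x + y); NaN when both counts are zero (undefined)."""
    if x_count + y_count == 0:
        return math.nan
    return (x_count - y_count) / (x_count + y_count)


def base_composition(seq: str) -> CompositionSummary:
    """Count bases of a nucleotide string (alphabet ACGTN, any case)."""
    s = seq.upper()
    counts = {b: 0 for b in "ACGTN"}
    for i, b in enumerate(s):
        if b not in counts:
            raise ValueError(f"illegal character {b!r} at position {i + 1}")
        counts[b] += 1
    summary = CompositionSummary(
        counts["A"], counts["T"], counts["G"], counts["C"], counts["N"]
    )
    if summary.total == 0:
        raise ValueError("empty or all-N sequence: composition undefined")
    return summary


def codon_position_composition(pcg_seqs: Sequence[str],
                               gene_names: Optional[Sequence[str]] = None
                               ) -> dict[int, CompositionSummary]:
    """Pooled base composition at codon positions 1/2/3 across genes.

    Sequences must be in-frame coding sequences (coding orientation);
    a trailing incomplete codon of 1-2 nt is dropped.
    """
    pools = {1: "", 2: "", 3: ""}
    for idx, seq in enumerate(pcg_seqs):
        name = gene_names[idx] if gene_names else f"gene{idx + 1}"
        try:
            p1, p2, p3 = split_codon_positions(seq)
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from None
        pools[1] += p1
        pools[2] += p2
        pools[3] += p3
    return {pos: base_composition(s) for pos, s in pools.items()}


def region_composition(genome: Mitogenome, feature_class: str) -> Optional[CompositionSummary]:
    """Pooled composition of all features of one class, each in coding
    orientation, concatenated in genome order.  None if the class is absent."""
    feats = genome.table.by_class(feature_class)
    if not feats:
        return None
    seq = "".join(extract_region(genome, f) for f in feats)
    return base_composition(seq)


def comparative_composition_report(genomes: Sequence[Mitogenome]) -> pd.DataFrame:
    """Per-species region table: A+T% of whole genome / PCGs / tRNA / rRNA /
    control region plus whole-genome skews.  Missing regions yield "N/A"."""
    rows = []
    for g in genomes:
        whole = base_composition(g.sequence)
        row = {"species": g.accession, "Whole A+T%": round(whole.at_content, 1)}
        for label, fclass in (("PCGs A+T%", "PCG"), ("tRNA A+T%", "tRNA"),
                              ("rRNA A+T%", "rRNA"),
                              ("control region A+T%", "control_region")):
            comp = region_composition(g, fclass)
            row[label] = "N/A" if comp is None else round(comp.at_content, 1)
        row["AT-skew"] = round(whole.at_skew, 2)
        row["GC-skew"] = round(whole.gc_skew, 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")


def composition_report(named_summaries: Sequence[tuple[str, CompositionSummary]]
                       ) -> pd.DataFrame:
    """Assemble per-region summaries into a report table."""
    rows = {name: summary.as_row() for name, summary in named_summaries}
    return pd.DataFrame.from_dict(rows, orient="index")
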