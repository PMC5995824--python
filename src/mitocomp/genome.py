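"""Data model for circular annotated mitochondrial genomes.

Insect mitogenomes are compact circular molecules (~14-19 kb) carrying a
fixed complement of 37 genes (13 protein-coding genes, 22 tRNAs, 2 rRNAs)
plus one large non-coding control region.  This module holds the annotation
model and the bookkeeping operations that summarise such a genome:
feature lengths, intergenic spacers, gene overlaps and the strand census.

Coordinate convention: 1-based inclusive on the forward (J) strand, matching
the From/To columns of published annotation tables.  All gap arithmetic is
``gap = next.start - current.end - 1`` in position-sorted order, with the
wrap-around pair (last feature back to the first) closed using circular
arithmetic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "control_region")

#: strand aliases accepted on input -> canonical J/N
_STRAND_ALIASES = {
    "J": "J", "N": "N",
    "F": "J", "R": "N",
    "+": "J", "-": "N",
}


class ParseError(ValueError):
    """Malformed annotation input; message names the offending record."""


class TableOnlyGenomeError(ValueError):
    """Raised when a sequence-level operation is requested on a genome
    that carries annotations only."""


@dataclass(frozen=True)
class Feature:
    """One annotated gene or region on the circle.

    ``start``/``end`` are 1-based inclusive.  ``end >= start`` for ordinary
    features; a wrap-around feature crossing the origin has ``start > end``.
    ``strand`` is "J" (majority/forward) or "N" (minority/reverse).
    """

    name: str
    start: int
    end: int
    strand: str
    feature_class: str
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"{self.name}: unknown feature class {self.feature_class!r}"
            )

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: Optional[int] = None) -> int:
        """Feature length in bp; wrap-around features need ``genome_length``."""
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name}: wrap-around feature needs genome_length")
        return genome_length - self.start + 1 + self.end


@dataclass(frozen=True)
class GapRecord:
    """Signed intergenic distance between two consecutive features.

    Positive = spacer of that many bp, negative = overlap, 0 = contiguous.
    """

    upstream: str
    downstream: str
    gap_bp: int


@dataclass
class AnnotationTable:
    """Ordered feature collection for one circular genome.

    Features are kept sorted by start (ties: end descending, then name) so
    that spacer/overlap statistics are deterministic.
    """

    genome_length: int
    features: list[Feature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        for f in self.features:
            if f.end > self.genome_length or f.start > self.genome_length:
                raise ValueError(
                    f"{f.name}: coordinates {f.start}..{f.end} exceed "
                    f"genome length {self.genome_length}"
                )
        self.features = sorted(
            self.features, key=lambda f: (f.start, -f.end, f.name)
        )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, feature_class: str) -> list[Feature]:
        return [f for f in self.features if f.feature_class == feature_class]

    @property
    def genes(self) -> list[Feature]:
        """All features except the control region (the 37 genes of a
        complete animal mitogenome)."""
        return [f for f in self.features if f.feature_class != "control_region"]


@dataclass
class Mitogenome:
    """A (possibly table-only) annotated mitochondrial genome."""

    table: AnnotationTable
    sequence: Optional[str] = None
    accession: str = ""

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
            if len(self.sequence) != self.table.genome_length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared "
                    f"genome length {self.table.genome_length}"
                )

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None


# ---------------------------------------------------------------------------
# Accounting operations
# ---------------------------------------------------------------------------

def intergenic_gaps(table: AnnotationTable) -> list[GapRecord]:
    """Signed gaps between consecutive features in position order.

    Returns one record per consecutive pair plus, for circular tables, the
    wrap-around pair (last feature -> first feature), so the record count
    equals the feature count.  Fewer than two features -> empty list.
    """
    feats = table.features
    if len(feats) < 2:
        return []
    records = []
    for up, down in zip(feats, feats[1:]):
        records.append(GapRecord(up.name, down.name, down.start - up.end - 1))
    if table.circular:
        last, first = feats[-1], feats[0]
        wrap = first.start + table.genome_length - last.end - 1
        records.append(GapRecord(last.name, first.name, wrap))
    return records


def spacer_summary(table: AnnotationTable) -> dict:
    """Count/total/max of the positive (spacer) gaps."""
    pos = [g for g in intergenic_gaps(table) if g.gap_bp > 0]
    longest = max(pos, key=lambda g: g.gap_bp, default=None)
    return {
        "count": len(pos),
        "total_bp": sum(g.gap_bp for g in pos),
        "max_bp": longest.gap_bp if longest else 0,
        "max_pair": (longest.upstream, longest.downstream) if longest else None,
    }


def overlap_summary(table: AnnotationTable) -> dict:
    """Count/total/max of the negative (overlap) gaps.

    Max-overlap ties break to the first pair in position order.
    """
    neg = [g for g in intergenic_gaps(table) if g.gap_bp < 0]
    best = None
    for g in neg:  # first-in-order wins ties
        if best is None or -g.gap_bp > -best.gap_bp:
            best = g
    return {
        "count": len(neg),
        "total_bp": sum(-g.gap_bp for g in neg),
        "max_bp": -best.gap_bp if best else 0,
        "max_pair": (best.upstream, best.downstream) if best else None,
    }


def strand_census(table: AnnotationTable) -> dict:
    """Gene counts per strand and per feature class.

    The control region is non-coding and excluded; for a complete animal
    mitogenome the class totals sum to 37.
    """
    census = {
        "J": {"PCG": 0, "tRNA": 0, "rRNA": 0, "total": 0},
        "N": {"PCG": 0, "tRNA": 0, "rRNA": 0, "total": 0},
    }
    for f in table.genes:
        census[f.strand][f.feature_class] += 1
        census[f.strand]["total"] += 1
    return census


def extract_region(genome: Mitogenome, feature: Feature) -> str:
    """Nucleotide sequence of a feature in its coding orientation.

    N-strand features are reverse-complemented; wrap-around features
    concatenate the end of the circle with its start.
    """
    if genome.sequence is None:
        raise TableOnlyGenomeError(
            f"cannot extract {feature.name}: genome {genome.accession or '?'} "
            "is table-only (no sequence)"
        )
    seq = genome.sequence
    if feature.wraps:
        raw = seq[feature.start - 1:] + seq[:feature.end]
    else:
        raw = seq[feature.start - 1:feature.end]
    if feature.strand == "N":
        raw = str(Seq(raw).reverse_complement())
    return raw


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------
#
# TSV dialect (tab-separated, '#' comments):
#   #genome_length=16175            <- optional pragma; otherwise max(end)
#   name  start  end  strand  class  codons
# 'strand' accepts J/N, F/R or +/-.  'codons' is "start/stop" for PCGs
# (either half may be empty), "." or empty otherwise.

def _canonical_strand(sym: str, record: str) -> str:
    try:
        return _STRAND_ALIASES[sym.strip()]
    except KeyError:
        raise ParseError(f"{record}: unknown strand symbol {sym!r}") from None


def parse_feature_tsv(source: Union[str, Path, io.TextIOBase]) -> AnnotationTable:
    """Read the 6-column annotation TSV dialect into an AnnotationTable."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    declared_length = None
    features = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#genome_length="):
                declared_length = int(line.split("=", 1)[1])
            continue
        parts = line.split("\t")
        if parts[0].lower() == "name":  # header row
            continue
        if len(parts) < 5:
            raise ParseError(f"line {lineno}: expected >=5 tab-separated fields")
        name, start_s, end_s, strand_s, fclass = parts[:5]
        codons = parts[5].strip() if len(parts) > 5 else ""
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(
                f"line {lineno} ({name}): non-integer coordinates"
            ) from None
        if start < 1 or end < 1:
            raise ParseError(f"line {lineno} ({name}): coordinates must be >= 1")
        start_codon = stop_codon = None
        if codons and codons != ".":
            head, _, tail = codons.partition("/")
            start_codon = head or None
            stop_codon = tail or None
        try:
            feat = Feature(
                name=name,
                start=start,
                end=end,
                strand=_canonical_strand(strand_s, f"line {lineno} ({name})"),
                feature_class=fclass,
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        features.append(feat)
    if not features:
        raise ParseError("no features found in annotation table")
    seen = {}
    for f in features:
        key = (f.name, f.start, f.end, f.strand)
        if key in seen:
            raise ParseError(f"duplicate feature record: {f.name} {f.start}..{f.end}")
        seen[key] = f
    length = declared_length or max(max(f.start, f.end) for f in features)
    try:
        return AnnotationTable(genome_length=length, features=features)
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def write_feature_tsv(table: AnnotationTable, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write the TSV dialect produced by :func:`parse_feature_tsv`."""
    lines = [f"#genome_length={table.genome_length}",
             "name\tstart\tend\tstrand\tclass\tcodons"]
    for f in table.features:
        if f.start_codon or f.stop_codon:
            codons = f"{f.start_codon or ''}/{f.stop_codon or ''}"
        else:
            codons = "."
        lines.append(
            f"{f.name}\t{f.start}\t{f.end}\t{f.strand}\t{f.feature_class}\t{codons}"
        )
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


_GENBANK_CLASS_MAP = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
}


def parse_genbank(source: Union[str, Path, io.TextIOBase]) -> Mitogenome:
    """Read a GenBank flat file into a :class:`Mitogenome`.

    CDS/tRNA/rRNA features map to PCG/tRNA/rRNA; D-loop or a misc_feature
    whose note mentions a control/A+T-rich region maps to control_region.
    Start/stop codon strings are taken from explicit note qualifiers when
    present ("start_codon:XXX", "stop_codon:XXX"); they are never inferred
    from sequence context.
    """
    record = SeqIO.read(source, "genbank")
    features = []
    for gb_feat in record.features:
        fclass = _GENBANK_CLASS_MAP.get(gb_feat.type)
        if fclass is None and gb_feat.type == "misc_feature":
            note = " ".join(gb_feat.qualifiers.get("note", [])).lower()
            if "control region" in note or "a+t-rich" in note or "at-rich" in note:
                fclass = "control_region"
        if fclass is None:
            continue
        quals = gb_feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [gb_feat.type])[0]
        start_codon = stop_codon = None
        for note in quals.get("note", []):
            for chunk in note.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("start_codon:"):
                    start_codon = chunk.split(":", 1)[1].strip().upper()
                elif chunk.startswith("stop_codon:"):
                    stop_codon = chunk.split(":", 1)[1].strip().upper()
        loc = gb_feat.location
        strand = "N" if loc.strand == -1 else "J"
        features.append(Feature(
            name=name,
            start=int(loc.start) + 1,  # Biopython is 0-based half-open
            end=int(loc.end),
            strand=strand,
            feature_class=fclass,
            start_codon=start_codon,
            stop_codon=stop_codon,
        ))
    if not features:
        raise ParseError(f"{record.id}: no annotatable features in GenBank record")
    table = AnnotationTable(genome_length=len(record.seq), features=features)
    return Mitogenome(table=table, sequence=str(record.seq), accession=record.id)


def parse_feature_table(
    source: Union[str, Path],
    sequence: Optional[str] = None,
    accession: str = "",
) -> Mitogenome:
    """Load a mitogenome from a GenBank flat file or annotation TSV.

    Format is sniffed from the content (GenBank files start with LOCUS).
    A TSV table yields a table-only genome unless ``sequence`` is given.
    """
    path = Path(source)
    head = path.read_text()[:2048].lstrip()
    if head.startswith("LOCUS"):
        return parse_genbank(path)
    table = parse_feature_tsv(path)
    return Mitogenome(table=table, sequence=sequence, accession=accession or path.stem)


def write_gap_report(table: AnnotationTable, path: Union[str, Path, io.TextIOBase]) -> None:
    """TSV spacer/overlap report: one row per consecutive feature pair."""
    lines = ["upstream\tdownstream\tgap_bp\tkind"]
    for g in intergenic_gaps(table):
        kind = "spacer" if g.gap_bp > 0 else ("overlap" if g.gap_bp < 0 else "contiguous")
        lines.append(f"{g.upstream}\t{g.downstream}\t{g.gap_bp}\t{kind}")
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def write_regions_fasta(
    genome: Mitogenome,
    features: Iterable[Feature],
    path: Union[str, Path, io.TextIOBase],
) -> None:
    """Extracted feature sequences (coding orientation) as FASTA."""
    chunks = []
    for f in features:
        seq = extract_region(genome, f)
        chunks.append(f">{f.name} {f.start}..{f.end} strand={f.strand}\n{seq}\n")
    text = "".join(chunks)
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)
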