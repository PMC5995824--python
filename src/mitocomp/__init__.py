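"""mitocomp: comparative analysis of annotated mitochondrial genomes.

Annotation-table accounting (spacers, overlaps, strand census), base
composition and AT/GC skew, codon usage and RSCU under the invertebrate
mitochondrial code, K2P and Nei-Gojobori divergence, neighbor-joining
phylogeny with bootstrap, and control-region motif detection — plus a
synthetic-data module so every stage is testable without downloads.
"""

from importlib import resources

from .genome import (
    AnnotationTable,
    Feature,
    GapRecord,
    Mitogenome,
    ParseError,
    TableOnlyGenomeError,
    extract_region,
    intergenic_gaps,
    overlap_summary,
    parse_feature_table,
    parse_feature_tsv,
    parse_genbank,
    spacer_summary,
    strand_census,
    write_feature_tsv,
)

__version__ = "0.1.0"


def load_reference_table() -> AnnotationTable:
    """The packaged Liriomyza chinensis (MG252777) annotation table."""
    ref = resources.files("mitocomp.data") / "liriomyza_chinensis_mg252777.tsv"
    with resources.as_file(ref) as path:
        return parse_feature_tsv(path)
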