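Deposited nucleotide sequences are not redistributed with this package.

To enable the sequence-level checks in tests/test_acceptance.py, place
here:

  MG252777.fasta        the Liriomyza chinensis mitogenome (GenBank
                        MG252777), plain FASTA
  pcg13_alignment.fasta codon alignment of the concatenated 13
                        protein-coding genes (stop codons stripped) for
                        the six Agromyzidae mitogenomes and the
                        Drosophila melanogaster outgroup, with record ids
                        L_sativae, L_trifolii, L_bryoniae,
                        L_huidobrensis, L_chinensis, C_horticola,
                        D_melanogaster

e.g. via NCBI EDirect:
  efetch -db nucleotide -id MG252777 -format fasta > MG252777.fasta
(comparators: HQ333260.1, GU327644.1, JN570504.1, JN570505.1, KR047789,
U37541.1), then extract the annotated CDS features in genome order and
align codon-aware (e.g. mafft on translations).
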