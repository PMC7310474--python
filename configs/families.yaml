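# Reproduction plan for the eight curated class II/III SLRP alignments.
#
# Place the curated, signal-peptide-removed family alignments under
# data/supplementary/<family>.fasta (optionally with a sidecar
# <family>.clades.tsv mapping sequence id -> taxonomic class; without one,
# classes are inferred from UniProt organism mnemonics, which covers only
# the species in the shipped mnemonic map).
#
# Reference ids are the human UniProt accessions; signal-peptide lengths
# are the UniProt annotations (edit if your alignment uses a different
# mature start).
out_dir: results/families
families:
  - family: fibromodulin
    alignment: data/supplementary/fibromodulin.fasta
    clade: amniotes
    regions: [n_terminal]
    reference: {id: Q06828, signal_peptide_length: 18}
  - family: lumican
    alignment: data/supplementary/lumican.fasta
    clade: jawed_vertebrates
    regions: [n_terminal]
    reference: {id: P51884, signal_peptide_length: 18}
  - family: osteoadherin
    alignment: data/supplementary/osteoadherin.fasta
    clade: bony_vertebrates
    regions: [n_terminal]
    reference: {id: Q99983, signal_peptide_length: 19}
  - family: osteoadherin_c
    alignment: data/supplementary/osteoadherin.fasta
    clade: tetrapods
    regions: [c_terminal]
    reference: {id: Q99983, signal_peptide_length: 19}
  - family: keratocan
    alignment: data/supplementary/keratocan.fasta
    clade: tetrapods
    regions: [n_terminal]
    reference: {id: O60938, signal_peptide_length: 20}
  - family: prelp
    alignment: data/supplementary/prelp.fasta
    clade: jawed_vertebrates
    regions: [n_terminal]
    reference: {id: P51888, signal_peptide_length: 20}
  - family: mimecan
    alignment: data/supplementary/mimecan.fasta
    clade: tetrapods
    regions: [n_terminal]
    reference: {id: P20774, signal_peptide_length: 19}
  - family: epiphycan
    alignment: data/supplementary/epiphycan.fasta
    clade: bony_vertebrates
    regions: [n_terminal]
    reference: {id: Q99645, signal_peptide_length: 21}
  - family: opticin
    alignment: data/supplementary/opticin.fasta
    clade: bony_vertebrates
    regions: [n_terminal]
    reference: {id: Q9UBM4, signal_peptide_length: 19}
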