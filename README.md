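# sulfoscan

Conservation-based prediction of sulfation-prone tyrosines in the
variable N- and C-terminal regions of aligned protein families, built for
the class II and III small leucine-rich repeat proteins (SLRPs:
fibromodulin, lumican, osteoadherin, keratocan, PRELP, mimecan,
epiphycan, opticin) but applicable to any family whose repeat core is
bounded by conserved cysteines.

Tyrosine sulfation is hard to observe directly (the modification is
labile in standard mass-spectrometry workflows), and single-sequence
predictors perform poorly on these proteins. `sulfoscan` instead asks an
evolutionary question: which tyrosines in the terminal regions are
conserved across a taxonomic clade *together with* the flanking residue
types known to promote sulfation? Given a gapped FASTA alignment of
mature sequences (signal peptides removed) and a clade assignment, a
tyrosine column at logo position *i* is predicted as sulfation-prone
when all three cut-offs hold:

1. **conservation** — %Y(*i*) ≥ 75, with gaps counting against
   conservation;
2. **context** — over the columns *i* ± 5, classifying each by its
   consensus residue, promoting/(promoting + suppressing) ≥ 0.5, where
   promoting = {Y} ∪ {E, D} ∪ {P, G, N, S} and suppressing =
   {R, K, H, F, W, I, M, V, L} ∪ {C};
3. **occupancy** — the column is non-gap in ≥ 50% of sequences.

Predicted columns are mapped to precursor residue numbers of a chosen
reference sequence (e.g. the human protein) by ungapped counting plus
the signal-peptide offset. The package also provides the surrounding
machinery: sequence curation rules, clade subsetting with column maps,
cysteine-anchor detection, per-column profiles and sequence-logo
matrices (equiprobable background, R = log2 20 − H), terminal-region
composition censuses, and a synthetic-alignment generator with planted
ground truth for end-to-end validation.

## Worked example

Generate a synthetic family (60 sequences, three tyrosine sites planted
at 95/85/80% conservation in promoting contexts, plus a 50%-conserved
decoy and a suppressed-context decoy) and run the predictor on its
N-terminal region:

```
$ sulfoscan simulate --seed 17 --out-prefix demo
60 sequences x 160 columns -> demo.fasta

$ sulfoscan predict --family demo --alignment demo.fasta \
    --clade jawed_vertebrates --clade-table demo.clades.tsv \
    --region n_terminal --reference-id syn0000_mammal --signal-length 18 -o out
demo n_terminal: predicted positions [10, 25, 40]
```

The three planted sites are recovered and both decoys are rejected. The
per-candidate diagnostics in `out/demo/n_terminal_predictions.tsv` show
why (`y_percent` is cut-off 1, `promoting_ratio` cut-off 2, `occupancy`
cut-off 3; the last columns are the mapped reference residue):

```
position  y_percent  occupancy  promoting_ratio  c1     c2     c3    predicted  ref
10        95         1.0        1.0              True   True   True  True       27 A
25        85         1.0        1.0              True   True   True  True       41 Y
40        75         1.0        1.0              True   True   True  True       55 Y
65        90         1.0        0.0              True   False  True  False      80 Y
```

Position 65 is the suppressed-context decoy: well conserved (90%) but
every neighbouring consensus residue is basic/hydrophobic, so the
context ratio is 0 and cut-off 2 fails — exactly the discrimination the
method is built on. The mapped reference column shows positions 25 and
40 as precursor tyrosines 41 and 55 of the chosen reference row (the
18-residue signal offset included); position 10 happens to map onto an
alanine in this particular reference sequence and is therefore listed
but excluded from reference-residue counts.

To analyse real curated family alignments, place them under
`data/supplementary/` and run the shipped plan (clade choice per family,
human reference accessions and signal-peptide lengths included):

```
sulfoscan run-all --config configs/families.yaml
```

which writes per-family profile/logo/prediction/census/mapping tables
and a cross-family summary counting distinct predicted human tyrosines.

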