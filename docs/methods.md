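# Methods

## The problem

Tyrosine sulfation is an extracellular post-translational modification
that is chemically labile under standard proteomic workflows, so
experimentally mapped sulfotyrosines are scarce. In the small leucine-rich
repeat protein (SLRP) family, the class II and III members carry
tyrosine-rich, acidic N- and (in one case) C-terminal regions outside the
conserved cysteine-bounded repeat core, and several of these tyrosines
are known to be sulfated. `sulfoscan` implements a comparative approach:
a tyrosine that mediates conserved protein–protein interactions through
its sulfate group should itself be conserved, together with the
surrounding residue types known to promote sulfation. The package
therefore predicts sulfation-prone tyrosines from a curated multiple
sequence alignment of one protein family, restricted to the taxonomic
clade in which the tyrosine cluster is conserved.

## Pipeline

1. **Curation** (`curation`): candidate (ungapped, mature) sequences are
   screened by six prerequisites: an explicit exclude list; the
   family-characteristic cysteine arrangement (an N-terminal cluster
   matching `C-x(2,3)-C-x-C-x(6,12)-C` by default, plus ≥ 2 downstream
   cysteines); no fragment flag; an annotated signal peptide (and an
   initiator methionine on precursor input); no unknown residues (`X`);
   one sequence per species and gene product. The cluster pattern is a
   configurable default, not a fixed constant, because published family
   definitions describe the cluster qualitatively; fragment and signal
   status come from database annotation and are therefore inputs.
2. **Clade subsetting** (`taxonomy`): each sequence is assigned one of six
   jawed-vertebrate classes, from a user table or from UniProt organism
   mnemonics. Named clades are fixed unions of classes (amniotes ⊂
   tetrapods ⊂ sarcopterygians ⊂ bony vertebrates ⊂ jawed vertebrates).
   Subsetting drops columns that are all-gap in the kept records and
   returns a column map to the original alignment. Positions in every
   report are numbered on the subset columns (1-based), which is what
   sequence-logo software displays; the original column is always
   recoverable through the map.
3. **Region extraction** (`regions`): anchor columns are those whose
   non-gap residues are ≥ 90% cysteine at ≥ 50% occupancy (threshold
   configurable). The N-terminal region is columns 1 to first-anchor − 1;
   the C-terminal region is last-anchor + 1 to the end. Anchoring is done
   on the clade subset being analysed; on the synthetic benchmark this is
   verified to commute with subsetting because anchors are planted
   gap-free in every class.
4. **Column statistics** (`conservation`): per-column residue counts,
   occupancy, consensus (ties broken alphabetically and flagged), and
   integer conservation percentages rounded half-up. The default
   denominator is *all* subset sequences, i.e. gaps count against
   conservation; the non-gap variant is always reported alongside. The
   residue classes used throughout are: tyrosine; acidic (E, D);
   turn-inducing (P, G, N, S); basic/hydrophobic (R, K, H, F, W, I, M, V,
   L); cysteine; neutral (Q, A, T). `X` is treated as neutral so it never
   counts for or against a context.
5. **Prediction** (`sulfo_predict`): a tyrosine column is predicted as
   sulfation-prone when all three cut-offs pass —
   * **C1**: tyrosine conservation ≥ 75% (all-sequence denominator);
   * **C2**: among the ±5 context columns, classified by their consensus
     residue, promoting/(promoting + suppressing) ≥ 0.5. Tyrosine counts
     as promoting (sulfotyrosines cluster); neutral-consensus columns are
     excluded from the ratio; columns below the occupancy floor are
     excluded; the window truncates at region edges; the candidate's own
     column never contributes. A window with no classifiable column
     passes with an explicit `indeterminate_context` flag rather than
     silently deciding either way;
   * **C3**: occupancy of the tyrosine column ≥ 50%.
   Advisory flags (consensus cysteine within ±7; N-x-S/T sequon with
   x ≠ P in the ±7 consensus) are recorded but never change the decision,
   since the underlying evidence ranks them as secondary features.
6. **Reference mapping** (`coord_map`): a predicted column is mapped to
   precursor numbering of a chosen reference sequence by counting the
   reference row's non-gap characters up to the column and adding the
   signal-peptide length. Columns where the reference is gapped map to
   `None` and are reported but excluded from reference-residue counts —
   a real outcome for clade-conserved sites absent from the reference.
7. **Census** (`census`): per-sequence region lengths, Y/P/R/K/D/E
   counts, and first-mature-residue identity (an N-terminal glutamine
   cyclises to pyroglutamate and protects against aminopeptidase
   trimming, hence the dedicated check).

## Synthetic benchmark

`synthetic_data.generate_family` builds alignments with the structure the
analysis assumes: a 70-column N region, a planted cysteine cluster
(`C-xx-C-x-C-x8-C`) and C-terminal cysteine pair (all 100% conserved), a
30-column core, and a 40-column C region, over 60 sequences spread across
five taxonomic classes by default. Tyrosine sites are planted as
per-sequence Bernoulli draws at configured conservation levels (defaults
0.95/0.85/0.80), each with ±5 context cells drawn from a promoting pool
(E, D, P, G, N, S) with probability `promoting_fraction` (default 0.8)
and otherwise from the suppressing pool (R, K, H, F, W, I, M, V, L). Two
decoys are planted: one at 50% conservation, one at 90% conservation with
a fully suppressing context, so both the conservation and the context
cut-off are exercised. Background cells are uniform over the 19 non-C
amino acids (no accidental anchors); off-draws at site columns also
exclude Y so a site's realised Bernoulli level equals its configured
conservation. Gaps are i.i.d. per cell (default 5%) except at anchor and
site columns, which stay gap-free so ground truth remains interpretable.
Clade-specific insertion blocks (all-gap outside the designated classes)
emulate lineage-specific terminal extensions.

What the generator does *not* emulate: phylogenetic correlation between
sequences (no tree, no substitution model), realistic indel structure
(gaps are i.i.d., not block-wise), and compositional drift along the
region. Passing the synthetic benchmark therefore demonstrates that the
rules and the coordinate bookkeeping are implemented correctly, not that
the biological prediction is valid on real families — that validation
comes from re-running the pipeline on curated family alignments.

## Recovery statistics and the binomial tail

With 60 sequences, a site planted at conservation *p* realises a column
tyrosine fraction that is Binomial(60, *p*)/60. Near the 75% cut this
matters: at *p* = 0.85 the realised fraction falls below the cut in about
1.4% of draws, and at *p* = 0.80 in about 10%, so no finite-sample
experiment can show 100% *marginal* sensitivity at those levels over
hundreds of replicates. The deterministic guarantee the three cut-offs
give is conditional: every planted column whose realised tyrosine
fraction is ≥ 0.85 and occupancy ≥ 0.9, with a promoting context, is
recovered. `recovery_experiment` therefore reports both the marginal
sensitivity (which tracks the exact binomial tail; a dedicated test
checks this against `scipy.stats.binom` at a level near the cut) and the
conditional ("qualified") sensitivity, which is 1.0. False recovery of a
50%-conserved decoy requires a ≥ 75% realised fraction, whose
probability at n = 60 is ≈ 7 × 10⁻⁵ per replicate — effectively zero over
the 100-replicate experiments used here.

## Numerical and edge-case conventions

* Conservation percentages round half-up (62/63 → 98, 21/22 → 95);
  consensus ties break alphabetically and are flagged.
* Logo information content uses the equiprobable background,
  R = log2(20) − H over non-gap frequencies, letter height = p·R, no
  small-sample correction by default (toggle available); all-gap columns
  get R = 0. Only the matrix is exported; rendering is out of scope.
* The predicted set is monotone in the C1 and C2 thresholds: raising
  either never adds a prediction. It is *not* monotone in the occupancy
  threshold, by construction: raising C3 also excludes low-occupancy
  columns from the C2 window, and removing a suppressing column (or
  emptying the window into the indeterminate-pass state) can flip a
  failing candidate to passing. This interaction is deliberate — on real
  clade subsets, sparse columns carry little evidence either way — and is
  surfaced in the diagnostics (`window_used`, `indeterminate_context`).
* Anchor detection on a clade subset (rather than the full alignment)
  is the default in the pipeline; the synthetic tests verify the two
  orders agree when anchors are present in all classes.
* `.` is accepted as a gap on input and written as `-`; residues are
  uppercased; `X` is tolerated by the parser so that the curation rule
  rejecting it is observable.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
families of 60 sequences × 160 columns, 100-replicate recovery
experiments, 1000-position coordinate round-trips, and 50 × 50
brute-force profile checks. These sizes give exact or
negligible-variance checks for every property while completing in
seconds. Analyses of real curated family alignments (hundreds of
sequences) use the same code paths and are configured through
`configs/families.yaml`.

## Known limitations

* Clade assignment is data, not inference; the shipped mnemonic map
  covers only commonly used model and reference species, and anything
  unmapped becomes `unassigned` (excluded from every clade subset).
* The context rule classifies a column by its consensus residue only; a
  50/50 split column contributes as whichever residue wins the
  alphabetical tie-break (the tie is flagged in the profile).
* Signal-peptide lengths are configuration; wrong lengths shift all
  precursor numbers by a constant, which the mapping table makes easy to
  spot against known anchors.
* Secondary structure and disorder, which also influence sulfation, are
  not modelled; the rules operate on sequence conservation alone.
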