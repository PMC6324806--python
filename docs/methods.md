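# Methods

## Problem and model

A protease hydrolyzes specific amide ("scissile") bonds of peptide
substrates, directed mainly by the residues around the bond.  `scissile`
treats cleavage-site prediction as a binary classification problem over
*cleavage windows*: for each bond, the 2k structural blocks flanking it
(k = 1 → P1–P1', k = 4 → P4–P4' in Schechter–Berger numbering, scissile
bond between P1 and P1') are featurized by concatenating per-block
physicochemical descriptor vectors, and a classifier estimates the
probability that the bond is cleaved.  A *structural block* generalizes
"residue" to any fragment between consecutive amide bonds, so non-natural
building blocks are supported whenever a descriptor row exists for them.

A linear peptide of L blocks has L−1 bonds and max(0, L−2k+1) full
windows; a 100-mer yields 93 P4–P4' and 99 P1–P1' windows.  Bonds within
k−1 blocks of a terminus have no full window: they are not represented as
training instances and receive predicted probability 0, the same
convention applied to external scores that a method does not produce.
Cyclic peptides close the chain with one extra bond and take wrap-around
windows (L windows for L blocks).

## Descriptors

Descriptors are data, not computation: any CSV mapping block names to
fixed-length real vectors is accepted, so proprietary molecular-
interaction-field descriptor sets plug in unchanged.  The shipped default
covers the 20 natural amino acids with six published experimental scales —
residue volume (Å³, Zamyatnin), Kyte–Doolittle hydropathy, Grantham
polarity, isoelectric point, net side-chain charge at pH 7, and an
aromaticity indicator — spanning the size / hydrophobicity / polarity /
charge axes that molecular-field descriptors summarize.  No scaling is
applied to the table by default (`DescriptorTable.zscaled()` is available);
the scale-sensitive classifier backends standardize features internally
per training subset instead, which keeps the table exchangeable while
making logistic-regression and RBF-SVM fits well-conditioned.  Block
similarity (for similarity-based frequency search) defaults to cosine,
which is robust to the heterogeneous units across descriptor columns;
euclidean distance is available.

## Frequency analysis

Simple frequency analysis (sFA) counts, per distinct window pattern, how
many times it occurs among all windows of all substrates (`found`) and how
many occurrences coincide with an observed cleavage (`cleaved`), plus a
multiplicity classification — per substrate carrying the pattern, whether
it was cleaved once, twice or more than twice.  Multiplicity is counted
per substrate occurrence: a pattern cleaved once in each of two substrates
counts "once" twice.  The position-occurrence matrix reports, for each
block and window position, the percentage of cleavage windows carrying
that block there; columns sum to 100 by construction.  Similarity
frequency analysis (SFA) matches patterns whose mean per-position block
similarity to a query reaches a threshold; the mean (rather than the
minimum) is used as the aggregation because it degrades gracefully when a
single position is substituted conservatively.

## Training-set construction

Substrates are split whole into train (default 80% of cleavage events) and
external sets, so no pattern leaks across the split through a shared
peptide.  The assignment shuffles substrates with a seeded generator,
greedily adds to train while that approaches the event target, then
applies a deterministic repair pass (single-substrate flips while they
reduce the deviation), which lands within one substrate's event count of
the target.

Window patterns are deduplicated; each unique pattern carries its
occurrence count M and is positive if any occurrence is cleaved.  Unique
negatives are partitioned into X = ceil(#negatives / #positives) seeded
random groups of the positive-pool size; the final short group is padded
by resampling (without replacement) from the other negatives so every base
classifier sees balanced classes, and every negative occurs in at least
one subset.  Each partition plus the full positive pool forms one training
subset.  Within a subset, every pattern is replicated

    N = max(1, round_half_up(11·M / (100 + M)))

times ("directed oversampling"): frequently met motifs are up-weighted,
saturating at 11 copies; the floor at one copy keeps rare motifs in every
subset.  The rounding rule is round-half-up in exact integer arithmetic
(N = (23M + 100) // (200 + 2M)); the constants 11 and 100 are exposed in
the code but not configuration-tuned.  Oversampling is applied within
subsets, after partitioning.

## Ensembles and evaluation

One base classifier is fitted per subset; the ensemble probability of a
bond is the mean of the base models' predicted cleavage probabilities for
its window.  Backends: logistic regression, RBF-kernel SVM, random forest
and gradient boosting, all at scikit-learn defaults.  The SVM's C and γ
are chosen per subset by 5-fold grid search (C ∈ {0.1, 1, 10, 100},
γ ∈ {scale, 0.01, 0.1, 1}) on ROC-AUC of decision values, then a sigmoid
(Platt) calibration maps decision values to probabilities.  Logistic
regression and the SVM standardize features inside the estimator pipeline.
Cross-validation is stratified 5-fold per subset; accuracy, sensitivity,
specificity, ROC-AUC, PR-AUC and MCC are averaged over folds, then over
subsets.  MCC with a zero denominator is defined as 0.

Rank-recovery evaluation: for each held-out peptide, bonds are sorted by
predicted probability (ties get the mid-rank; for P4–P4' models all
near-terminus bonds tie at 0 and share the bottom ranks), each known
cleavage site's rank is normalized by the peptide's bond count, and the
cumulative percentage of known sites recovered at or below each normalized
position is evaluated on a 0.01-step grid with ≤ comparisons.  The *best*
baseline assigns known sites ranks 1, 2, 3, … per peptide; the *random*
baseline averages curves from uniform-random scores over repetitions.
Family-level curves pool rank records across proteases.

## Synthetic study conditions

The generator draws peptide blocks i.i.d. uniformly over the alphabet,
with lengths uniform on [20, 40] (default); each bond with a full P4–P4'
window is cleaved independently with probability
expit(logit(base_rate) + strength · Σ_pos pref[block(pos), pos]).
The logistic link keeps the base rate interpretable and makes logistic
regression a well-specified learner, so parameter recovery is a meaningful
check.  The default protease is caspase-like with a strictly selective P1:
D at P1 carries +5 log-odds while every other block carries −4 (real
caspases cleave after aspartate near-exclusively), plus mild secondary
preferences (D at P4 +2, E at P3 +1.5, V at P2 +1.5, G at P1' +1.5) and
base rate 0.02.  Under these conditions ~99% of events are motif-driven,
the non-cleaved : cleaved window imbalance is ≥ 20:1, and the induced
position distribution (computed by Monte-Carlo weighting of random
windows) is the ground truth that occurrence matrices are checked against.

What the generator does **not** emulate: real substrate composition
(database substrates are not i.i.d. uniform sequences), correlations
between neighbouring residues, protein-level effects (solvent
accessibility, secondary structure, unfolding), and evidence-count
structure (all synthetic events have count 1).  Passing tests therefore
demonstrate that the pipeline recovers a position-specific specificity
signal under realistic imbalance — not that a given real protease will be
predicted with the same accuracy.

## Problem sizes and numerical choices

The standard study uses 500 substrates (≈ 11,000–12,000 P4–P4' windows,
≈ 450–500 events, ≈ 25–30 balanced subsets); the baseline-ordering check
uses 20 replicates of 120 substrates; the random baseline uses 1000
repetitions.  Degenerate cases: peptides shorter than a full window yield
zero windows (not an error); a training subset with a single class, a
fold with fewer minority members than folds, and an occurrence matrix with
zero usable events are errors; fewer negatives than positives yields one
short unpadded partition.  Model bundles record a content fingerprint of
the descriptor table, and prediction refuses a mismatched table.

## Known limitations

- Descriptor quality bounds everything: blocks indistinguishable in the
  table are indistinguishable to the classifier and to similarity search.
- The per-pattern deduplication labels a pattern positive if it is cleaved
  anywhere, so a pattern that is cleaved in one context and resistant in
  another contributes only its positive label.
- Oversampling replicates patterns exactly (no synthetic minority
  interpolation), by design.
- Evidence counts on events weight nothing during training; they are
  carried through I/O for downstream use.
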