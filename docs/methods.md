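# Methods

## Ground-truth construction

**Residue–residue interactions (RRIs).** Chains are read from PDB or
mmCIF with gemmi; the first model is used, waters are skipped,
alternate locations resolve to the highest-occupancy conformer (ties to
the lexicographically first altloc), and residues without any heavy
atom are dropped with a warning. Two residues across chains interact
iff the minimum Euclidean distance over their heavy atoms (C, N, O, S —
hydrogens never count) is **≤ cutoff**, default 6 Å (4 and 8 Å are the
usual sensitivity settings). The comparison is boundary-inclusive;
"within 6 Å" is not otherwise specified, and the boundary tests pin
this choice. The search uses a KD-tree over heavy atoms and is verified
in the test suite against an exhaustive all-atom-pairs scan.

**Exon–exon interactions (EEIs).** Exons are contiguous 1-based
inclusive segments in protein-sequence coordinates; a SIFTS-style
numbering map (author residue number → sequence position) is the only
coordinate conversion point, with identity numbering as the default. An
exon pair is *contact-interacting* iff at least one residue of each
exon forms an RRI with the other; with interface-residue sets from
external energy- or evolution-based callers, an exon pair interacts iff
each exon contains ≥ 1 interface residue of its chain (one residue is
deemed enough; no stricter overlap quantity is defined anywhere).
Exon pairs in which either exon has zero resolved residues are not
emitted at all: they are unobservable in the structure, not negative.
Transcript–protein correspondence is accepted only for a gapless,
mismatch-free full-length alignment, which is exactly string equality —
no alignment engine needed.

**Buried surface area.** SASA by Shrake–Rupley quadrature: each heavy
atom's probe-expanded sphere (radii C 1.70, N 1.55, O 1.52, S 1.80 Å;
probe 1.4 Å) is sampled with a deterministic golden-spiral point set
(960 points by default; the isolated-atom closed form 4π(r+p)² is
reproduced to ≲0.1%, and a 10,000-point run agrees within 2% on
clashing atoms). BSA = SASA(A) + SASA(B) − SASA(AB), clamped at 0. The
hard area rule classifies > 2200 Å² as biological and < 400 Å² as a
crystal-packing artifact; the band between is *indeterminate*, since
resolving it requires evolutionary evidence that is out of scope here.

**Harmonization.** A predicted chain is usable in place of an
experimental one only if the experimental residue sequence occurs
in order within the predicted sequence; the predicted chain is then
restricted to exactly those residues (greedy left-to-right subsequence
match — any valid identical-residue correspondence is acceptable, and
the greedy one is deterministic). Otherwise the pair is dropped.

## Score canonicalization

Three upstream output granularities map to one residue-pair matrix:
max over atom-pair scores, outer product of per-residue probabilities,
or direct residue-pair likelihoods. Missing entries are NaN — never 0,
because an unscored pair is absence of evidence. When an exon-pair
block is sliced out for post-processing, missing entries are imputed
with the **global matrix minimum**, so "no evidence" can never
masquerade as strong evidence. Scores are deliberately not renormalized
across predictors; decision thresholds are calibrated per model, so
scales need not be comparable.

## Post-processors

**PPMax** scores an exon pair by the maximum entry of its block:
parameter-free, monotone, and on the predictor's own scale.

**PPDL** is a small convolutional network on bilinearly resized blocks.
Architecture: 1×32×32 input → conv 16 @3×3 + ReLU + 2×2 max-pool →
conv 32 @3×3 + ReLU + pool → dense 64 + ReLU + dropout 0.25 → sigmoid.
Loss is binary cross-entropy with class weights inversely proportional
to class frequencies (exon-level data runs roughly 1:4
positive:negative, so positives are up-weighted); Adam at 1e-3, batch
32, up to 100 epochs with early stopping on validation AU-PRC
(patience 10). All parameters live in `PPDLConfig` and are
serialized with the weights, so the topology is replaceable without
touching code. Bilinear resizing was chosen over padding-to-max because
exon lengths span orders of magnitude; the interpolation is exact on
already-sized blocks, preserves constants, and stays inside the input
range. The network is implemented directly on numpy with hand-written
backprop; everything is float32 and driven by one seeded generator, so
training is bit-reproducible and serialization round-trips exactly.

**Novel-EEI flagging.** Predictions on unseen protein pairs are flagged
confident only if they score **strictly above** the maximum score the
model assigns to its training non-interacting pairs; an equal score
already has nonzero empirical false-discovery rate.

## Evaluation protocol

Chains are clustered at < 30% global sequence identity (MMSeqs2 cluster
TSVs are ingested directly; the built-in fallback is greedy
representative clustering, longest sequence first, identity = matches /
alignment length under a global alignment). Clusters — never chains —
are dealt to five folds in boustrophedon order 1,…,k,k,…,1 after
sorting by chain count, keeping fold sizes as even as possible. A
protein pair belongs to a fold only if *both* chains' clusters are in
that fold; cross-fold pairs are dropped as the conservative
leakage-free choice.

Decision thresholds are calibrated per model on training data: for each
nominal level t ∈ {1,…,5}%, the smallest observed score τ such that
FP/(FP+TP) ≤ t among training pairs scoring ≥ τ (+∞, i.e. predict
nothing, when unattainable). FDR proper — not an FPR quantile — is the
controlled quantity; `calibrate_thresholds(..., )` candidates are the
observed scores, ties resolved toward the higher threshold. Calibration
is per fold-model. Reported measures: AU-ROC (rank statistic, ties
half), AU-PRC (step interpolation, with the positive-class fraction as
its random baseline), and MCC/precision/recall/F at each calibrated
threshold, zero denominators giving 0. Methods are compared with
two-sided paired Wilcoxon signed-rank tests (zero differences dropped)
and Benjamini–Hochberg correction.

## Synthetic generator

The generator plants ground truth rather than approximating nature.
Each chain's Cα trace runs along a straight line at 3.8 Å spacing, the
two lines parallel and separated by 2·cutoff + 8 Å. Residues of the
planted contact patch carry one CB pseudo-atom each, clustered inside a
< 2 Å ball at the interface midpoint, so *exactly* the patch pairs fall
below the cutoff and every other inter-chain pair is ≥ cutoff + 3.7 Å
away — the distance rule recovers the planted contact set exactly, for
any rectangular patch. Exon segmentations tile the sequence with
geometric lengths (mean 40 residues, a typical internal exon).
Score matrices draw interface pairs from Beta(8,2) and background pairs
from Beta(2,8) by default; equal parameters give the zero-signal null.
Defaults (chains 90–150 residues, 16-residue patches) put the
exon-level class balance at roughly 1:4 to 1:6.

What the fixtures do **not** emulate: real fold geometry, side-chain
packing, correlated predictor errors, or any specific upstream method's
score distribution. Passing tests therefore certify the bookkeeping,
calibration and learning machinery — not performance on real
structures. One instructive artifact: pushed through the structural
pipeline with zero score signal, PPMax still shows AU-ROC above chance,
because interacting exon pairs are systematically longer (an exon must
be long enough to host patch residues) and the maximum of a larger
block is stochastically larger. The zero-signal chance checks are
therefore run on generated blocks whose shapes are independent of their
labels; the size confound is a property of max-pooling post-processors
worth knowing about on real data too.

## Numerical conventions and sizes

0-based residue indices internally, author numbering preserved for I/O;
1-based inclusive exon coordinates. Contact comparisons are inclusive.
The permutation-null check permutes labels consistently across
training, validation and held-out data (the standard whole-dataset
permutation); chance level is then 0.5 with Monte-Carlo width set by
the held-out size. Test and acceptance runs use 500+500 training
blocks, 150+150 validation, 250–1000 per class held out, 2,000-point
score sets at 1:4 imbalance for calibration, and 10–20 replicate seeds
— sizes chosen so every check is sharp at desk scale while the whole
suite stays fast.

## Known limitations

- The energy-/evolution-based interface callers themselves are not run;
  their outputs are ingested from files.
- The greedy fallback clustering is quadratic in the number of
  sequences and meant for small chain sets; use MMSeqs2 output for
  anything large.
- The CNN is a compact CPU implementation; it is not meant for
  GPU-scale training or for transferring externally trained weights.
- BSA uses fixed per-element radii and heavy atoms only; absolute areas
  differ from PISA/EPPIC values, while the classification thresholds
  are taken as published.
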