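# exonppi

Exon-level prediction and evaluation of protein–protein interaction
interfaces.

Alternative splicing swaps exons in and out of proteins, and with them
whole stretches of potential binding interface. Residue-level interface
predictors answer "which residue pairs touch?"; many downstream
questions — does skipping this exon destroy this interaction? — are
asked at the exon level instead. `exonppi` is a toolkit for researchers
who want to lift residue-pair interface predictions to **exon–exon
interaction (EEI)** calls and evaluate them honestly:

- **Ground truth from structures.** Two residues r1, r2 of co-resolved
  chains interact (an RRI) iff any heavy atom (C, N, O, S) of r1 lies
  within 6 Å of any heavy atom of r2. Two exons e1, e2 interact iff
  some residue of e1 forms an RRI with some residue of e2.
  Buried-surface-area interface classification (crystal artifact
  < 400 Å² < indeterminate < 2200 Å² < biological) and harmonization of
  predicted against experimental structures are included.
- **Score canonicalization.** Upstream predictors emit atom-pair
  scores, per-residue interface probabilities, or residue-pair
  likelihoods; all three become one residue-pair score matrix
  (max over atom pairs / product of probabilities / direct).
- **Two post-processors.** For an exon pair's score block
  S ∈ R^(|e1|×|e2|): **PPMax** scores max_{i,j} S_ij; **PPDL** resizes
  S bilinearly to 32×32 and applies a small CNN trained with
  class-weighted cross-entropy and early stopping on validation AU-PRC.
- **Leakage-controlled evaluation.** Chains clustered at <30% sequence
  identity; whole clusters dealt to 5 folds in round-robin
  forward–backward order; decision thresholds calibrated on training
  data so the false discovery rate FP/(FP+TP) stays ≤ {1,…,5}%; AU-ROC,
  AU-PRC, MCC, precision, recall, F-score; paired Wilcoxon +
  Benjamini–Hochberg method comparison; background-maximum flagging of
  novel predictions.
- **A synthetic generator** that plants interfaces with exactly known
  contacts, exon segmentations, and score matrices, so every stage is
  testable end to end without external data.

## Worked example

```python
from exonppi import (SynthConfig, simulate_dataset, slice_exon_pair,
                     ppmax, au_roc)
from exonppi.exonmap import LABEL_INTERACTING

cfg = SynthConfig(seed=11, n_pairs=10)
labels, scores = [], []
for pair in simulate_dataset(cfg):
    for rec in pair.eei_records:
        block = slice_exon_pair(pair.matrix, pair.map1, pair.map2,
                                rec.exon1_id, rec.exon2_id)
        scores.append(ppmax(block).score)
        labels.append(int(rec.label == LABEL_INTERACTING))
print(len(labels), sum(labels), round(au_roc(labels, scores), 3))
```

prints `158 20 1.0`: 10 simulated protein pairs yield 158 observable
exon pairs of which 20 truly interact, and with strongly separated
score distributions (interface Beta(8,2) vs background Beta(2,8)) the
PPMax score ranks every interacting pair above every non-interacting
one (AU-ROC 1.0). The scripts in `examples/` walk through each
capability the same way — contacts from planted structures, exon
labeling and PPMax, CNN training and novel-EEI flagging, folds and
FDR-calibrated evaluation — and print what the numbers mean.

A thin CLI mirrors the library:

```sh
exonppi simulate --seed 3 --n-pairs 2 --out sim/
exonppi extract-rri --structure sim/P000.pdb --chains A,B --out rri.tsv
exonppi label-eei --rri rri.tsv --structure sim/P000.pdb --chains A,B \
    --exons sim/P000.exons_A.tsv,sim/P000.exons_B.tsv --out eei.tsv
```

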