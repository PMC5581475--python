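# contactrank

Two-stage protein residue–residue contact prediction with pairwise rank
fusion.

**Stage 1** scores each residue pair two ways: an ensemble of three random
forests trained on 4:1 under-sampled pools of windowed sequence features
(PSSM + profile side-columns, predicted secondary structure, solvent
accessibility, Atchley factors, relative position; two 9-residue windows per
pair), and externally computed correlated-mutations score matrices ingested
as files and min–max normalized per protein.

**Stage 2** fuses the stage-1 scores with a per-protein pairwise ranking
SVM: residue pairs of one target are ordered by their true inter-residue
distance (binned into ordinal relevance levels), the induced constraints
`w·Φ(d_i) ≥ w·Φ(d_j) + 1 − ξ` are reduced to difference vectors, and the
soft-margin objective `½‖w‖² + C Σ ξ` is solved exactly by dual coordinate
descent (duality-gap certified). One model per sequence-separation range
class: short (6–11), medium (12–23), long (≥ 24).

Contacts follow the CASP convention — Cβ (Cα for glycine) distance
strictly below 8 Å — and evaluation reports Top5 / L/10 / L/5 precision per
range class, macro-averaged over targets, with paired t-tests between
methods.

A synthetic-fixture generator (confined self-avoiding walks with native-like
~2–3 % contact density, score matrices with tunable signal, feature files
with a tunable planted signal) makes the whole pipeline trainable and
testable offline.

## CLI

```bash
# generate a toy data set (PDB-style coords, PSSM, SS, SA, CM triplet files)
contact-rank make-fixtures --n 20 --length 100 --seed 7 --out fixtures/

# train both stages for all three range classes
contact-rank train --fixtures fixtures/ --out models.joblib

# per-range variants
contact-rank train-rf     --fixtures fixtures/ --range long   --out rf_long.joblib
contact-rank train-ranker --fixtures fixtures/ --range medium --out rank_med.joblib

# predict: one CASP-RR file per range plus a merged file per target
contact-rank predict --model models.joblib --fixtures fixtures/ --rr-out preds/

# score predictions against structures
contact-rank evaluate --pred-dir preds/ --struct-dir fixtures/ --report report.tsv

# paired t-test + scatter table between two reports
contact-rank compare --report-a report.tsv --report-b other.tsv --range long --metric L5
```

Every training/prediction run writes its resolved configuration
(`*.config.yaml`) next to its outputs.

## Layout

| module | role |
| --- | --- |
| `contactrank.geometry` | contact maps, range classes, minimal PDB reader |
| `contactrank.io_formats` | PSSM / CM-matrix / CASP-RR / SS / SA readers & writers |
| `contactrank.features` | per-residue feature tables, windowed pair vectors |
| `contactrank.rf_stage` | under-sampling, RF ensembles, ensemble scoring |
| `contactrank.ranker` | rank examples, difference vectors, ranking-SVM solver |
| `contactrank.evaluation` | Top5 / L10 / L5 precision, t-tests, scatter tables |
| `contactrank.synthetic` | deterministic fixture generator |
| `contactrank.config`, `contactrank.pipeline`, `contactrank.cli` | configuration, orchestration, CLI |
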