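# owh-screen

Multi-modal screening analysis for organotypic brain-slice neuroprotection
studies. The package provides a tested, reusable implementation of six
analysis stages plus a seeded synthetic-data module so every stage can be
benchmarked against known ground truth without any external data:

- **`owh_screen.synthetic_data`** — seeded generators: DAPI-like nucleus
  fields with a pyknotic subpopulation, microglia-like cell masks from five
  parametric shape families, a 255-transcript expression panel with planted
  differential and emergent (combination-only) effects, and per-slice scalar
  outcomes with planted treatment effects.
- **`owh_screen.nuclei`** — pyknotic-nucleus quantification: intensity
  normalization + high-pass filtering, Laplacian-of-Gaussian blob detection
  with seeded watershed splitting, eight per-nucleus features (area,
  Crofton perimeter, ideal radius, eccentricity, three intensity scores,
  detection scale), and a random-forest pyknosis classifier with 1:3
  class-imbalance subsampling, 80:20 split and 5-fold CV.
- **`owh_screen.morpho`** — cell morphometrics: Otsu segmentation with
  25-pixel and border filters, quadrant splitting, stratified 80:20
  train/test assignment, nine morphology parameters, and a shape-mode model
  (50-point contour registration with Procrustes alignment, PCA, seeded
  k-means into 5 modes) with x5 count scaling.
- **`owh_screen.synergy`** — four-model drug-combination synergy verdicts
  (combination subthresholding, highest single agent, response additivity,
  Bliss independence) from per-slice outcomes, with seeded permutation
  p-values and a Bliss applicability flag when a monotherapy shows no effect.
- **`owh_screen.network`** — Gaussian graphical models: MLE precision matrix,
  partial correlations, Fisher-Z confidence-interval edge selection,
  condition-vs-variable networks, GraphML export.
- **`owh_screen.transcriptomics`** — geometric-mean normalization, Welch
  t-test differential expression vs a reference group, PCA with 95%-variance
  component selection and top-25 contributor tables, Venn partitions of DEG
  sets, the combination-only normalization filter, and hypergeometric
  gene-set enrichment with BH adjustment.
- **`owh_screen.emergence`** — detection of emergent combination effects:
  per-transcript prediction of combination-group expression from the four
  single-condition group means via gradient-boosted regression trees with
  10-fold pre-validated predictions, then OLS prediction intervals (95%/99%)
  and z-score difference reporting.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite: feature-equation
identities, detection/classification benchmarks, shape-mode family recovery,
synergy power/calibration simulations, network edge-recovery and type-I-rate
simulations, transcriptomics oracles, and emergence coverage/recovery
simulations. The full suite runs in a few minutes on one CPU.

## CLI

Everything is reachable through `owh-screen`:

```sh
# generate synthetic inputs
owh-screen simulate nuclei   --seed 1 --out data/
owh-screen simulate panel    --seed 1 --out data/
owh-screen simulate outcomes --seed 1 --out data/outcomes.csv

# nucleus pipeline
owh-screen nuclei detect --image data/nuclei.tiff --out detections.csv

# synergy verdict grid
owh-screen synergy --outcomes data/outcomes.csv --alpha 0.05 \
    --n-perm 10000 --seed 1 --out verdicts.csv

# partial-correlation network with optional condition node
owh-screen network --table vars.csv --condition group:control,OGD \
    --out edges.csv --graphml net.graphml

# transcriptomics
owh-screen degs --expression data/expression.csv --samples data/samples.csv \
    --group-a AzEpo --group-b OGD --out degs.csv
owh-screen pca --expression data/expression.csv --out contributions.csv
owh-screen emergence --expression data/expression.csv \
    --samples data/samples.csv --scope global --seed 1 --out emergence.csv
```

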