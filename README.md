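# cytopoint

Centre-point ("keypoint") multi-class cell detection for differential immune
cell counts on brightfield cytopathology tiles. A single click at each cell
centre is the only ground-truth modality; the pipeline turns those clicks
into class-adaptive Gaussian heatmap targets, trains a fully-convolutional
encoder–decoder with a penalty-reduced focal loss, decodes heatmap peaks
back into scored centre-point predictions, and evaluates them with
distance-threshold average precision, inter-rater ICC(A,1) and differential
leukocyte counts (with the >3% eosinophil / >61% neutrophil categorical
determinations).

The four cell classes are `macrophage_lineage`, `neutrophil`, `eosinophil`
and `lymphocyte`, with default reference diameters of 142 / 104 / 126 / 61 px
at the native 1024-px tile scale.

## Layout

| module | contents |
|---|---|
| `cytopoint.annotations` | annotation data model, CSV/JSON I/O, multi-assessor consensus merging (10-px dedup, majority vote, ties flagged), class-size config |
| `cytopoint.heatmap` | Gaussian target encoding (per-class sigma, element-wise max overlap) and peak decoding (connected components, cluster-area cap, argmax per cluster) |
| `cytopoint.model` | numpy encoder–decoder network (`resnet34_like` and CPU-scale `tiny` presets, pixel-shuffle upsampling, skip connections), focal loss, AdamW training loop with annotation-consistent augmentation |
| `cytopoint.evaluation` | greedy/optimal centre matching at δ·diameter, AP/F1 reports, ICC(A,1) with ANOVA components, differential counts, cytospin-level dataset splits |
| `cytopoint.synthetic` | seeded generator of cytospin-like tiles with exact truth annotations, simulated assessors (jitter / misses / class confusion) |
| `cytopoint.cli` | `cytopoint` command with `simulate`, `consensus`, `encode`, `train`, `predict`, `evaluate`, `count` subcommands |

The network is implemented directly in numpy (im2col convolutions with
explicit backward passes) so the whole pipeline runs on a single CPU with no
deep-learning framework dependency.

## CLI walk-through

```bash
# default per-class sizes (YAML)
cytopoint make-class-config --out classes.yaml

# 2 cytospins x 4 synthetic tiles + truth annotations + manifest
cat > sim.yaml <<EOF
scene: {tile_size: 64}
n_cytospins: 2
tiles_per_cytospin: 4
EOF
cytopoint simulate --config sim.yaml --out data/ --seed 1

# merge multi-assessor clicks into a consensus set
cytopoint consensus --annotations raw_clicks.csv --out consensus.csv

# encode targets, train, predict, evaluate, count
cytopoint encode  --annotations data/annotations.csv --classes classes.yaml \
                  --out heatmaps/ --out-size 64 --tile-size 64
cytopoint train   --tiles data/ --annotations data/annotations.csv \
                  --classes classes.yaml --config train.yaml --out model.npz --seed 1
cytopoint predict --model model.npz --tiles data/ --classes classes.yaml --out preds.csv
cytopoint evaluate --predictions preds.csv --truth data/annotations.csv \
                  --classes classes.yaml --out report.csv --tile-size 64
cytopoint count   --points preds.csv --manifest data/manifest.json --out counts.csv
```

Every subcommand derives its random stream from the global `--seed` via a
stage-name hash and writes a `.runlog.json` (config hash, seed, versions,
wall time) next to its main artifact.

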