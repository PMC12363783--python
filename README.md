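# infoconn

Informational-connectivity and training-transfer analysis for task fMRI,
with a fully synthetic data generator providing ground truth for every
stage.

The pipeline goes from single-trial response estimates (least-squares-
separate GLMs with motion censoring) through within-context
representational similarity matrices (RSMs), ROI-pair informational
connectivity matrices (ICMs), permutation/FDR edgewise group inference,
multivariate connectivity-profile distances, and behavioral training /
transfer learning-rate metrics.

## Modules

| module | what it does |
|---|---|
| `infoconn.design` | study layout: 3 training groups × pre/post sessions, 4 encoding + 4 retrieval runs, spatial/temporal contexts |
| `infoconn.synthetic` | atlas, trial-pattern, BOLD-run, and behavior-log generators with planted coupling effects |
| `infoconn.behavior` | training error normalization, transfer learning rates, training slopes, correlation machinery |
| `infoconn.estimation` | double-gamma HRF, LS-S designs and OLS fits, framewise displacement, frame/trial/run censoring |
| `infoconn.similarity` | Fisher-z cross-run within-context RSMs per ROI |
| `infoconn.connectivity` | ICMs, group × session edge contrasts, permutation null, BH-FDR |
| `infoconn.distance` | 1 − correlation between spatial and temporal connectivity profiles per ROI, paired session tests |
| `infoconn.pipeline` / `infoconn.cli` | config, end-to-end driver, manifest, Markdown report |

## CLI

All stages are available as `infoconn` subcommands:

```bash
infoconn simulate --seed 1 --n-rois 16 --n-per-group 4 --out patterns.h5
infoconn connectivity --patterns patterns.h5 --context all --out icms.h5
infoconn edge-contrast --icms icms.h5 --patterns patterns.h5 \
    --contrast verbal_memory --n-perm 10000 --seed 7 --out edges.csv
infoconn distance --spatial icms_sp.h5 --temporal icms_tp.h5 --out dist.csv
infoconn behavior --seed 2 --out metrics.csv
infoconn run-all --config config.yaml --out-dir run/
```

`run-all` reads a YAML config (seed, design, atlas, model/effects,
similarity, connectivity, behavior blocks) and writes edge tables,
distance tables, behavioral metrics, a JSON manifest with per-stage
counts, and a Markdown report. Identical seeds reproduce every output
bit-identically.

The BOLD path (`simulate-bold` → `estimate-trials`) exercises the
single-trial estimator end-to-end on synthetic runs with events.tsv and
6-column motion `.par` files.

## Conventions worth knowing

- RSMs pair trials **across runs only** and **within context only**
  (including the pooled "all" type); Fisher z is clipped at |r| = 1 − 1e-7.
- Edge inference permutes participant group labels (add-one p
  estimator), contrasts the target group against the pooled others with
  Welch t, and controls FDR with Benjamini–Hochberg per contrast family.
- Distance session tests report **post − pre** (positive t = greater
  post distance between spatial and temporal connectivity profiles).
- Censoring: FD > 0.9 mm flags a frame; a trial is dropped if a flagged
  frame falls in its modeled response window; a run is dropped if > 20%
  of frames are flagged or absolute displacement exceeds 1.25 mm.
- Behavior: navigation training error is
  100 × (traveled − shortest)/(1.2 × shortest); transfer error is
  (traveled − optimal)/optimal; Eq-style learning rates are
  −(first − last)/(first + last) over session halves (navigation) and
  (last − first)/n_trials (verbal recall).
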