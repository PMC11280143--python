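# brainsync

Whole-brain structural/functional connectivity analysis toolkit: atlas-based
quantification of axon-label and activity-marker signals, structure-wise
nonparametric comparisons, a rewiring/activity correlation classifier with
reshuffled nulls, significance-gated interregional correlation networks with
Louvain community analysis, and exact paired behavior statistics — all
exercisable end to end on synthetic cohorts generated in-package.

## Modules

| module          | what it does |
|-----------------|--------------|
| `synthdata`     | toy labeled atlases (multi-page TIFF masks), four-group cohorts of AP-binned negative-binomial counts with planted genotype effects, latent-factor correlation communities, rewiring-coupled regions, rendered section images, paired behavior tables |
| `segmentation`  | axon-pixel binarization (probability-weighted, Gaussian edge enhancement, global 6×SD threshold), rolling-ball background subtraction, Laplacian-of-Gaussian spot detection (10 µm diameter, 2×SD threshold) |
| `quantify`      | compartmentalization of pixels/spots into atlas regions, 100-µm AP binning, region-selection filters (13×SD + 20th percentile; >100 cells), volume-based densities with the 800 cells/mm³ exclusion and baseline normalization |
| `structurewise` | Friedman repeated-measures tests (blocks = AP bins, conditions = groups), Wilcoxon post hocs with one-step Bonferroni correction, signed sum-of-differences effect metric |
| `rewire`        | pairwise difference traces, second-order difference traces, Pearson correlation of mean traces, 1,000× bin-reshuffled nulls, three-criterion positive/negative/none classification |
| `fosnet`        | two-sided Kendall tau-b matrices gated at p < 0.05 (exact p for small untied samples), graph construction, degree centrality and participation coefficient, threshold-stability sweeps, area summaries, subnetwork extraction |
| `communities`   | Louvain detection on the positive-weight subgraph, resolution tuning by max mean (Q − Q_shuffled) against endpoint-shuffled surrogates over R = 0.4–0.9, community-level correlation summaries |
| `behavior`      | frame-label aggregation to durations; exact two-tailed Wilcoxon signed-rank tests (full 2^n sign-assignment null) |
| `qc`            | KNN injection-site separability with stratified CV and a label-shuffled null |
| `cli`           | stage subcommands + end-to-end demo over a YAML config with a single root seed |

## CLI

```sh
brainsync --outdir out --seed 7 demo           # simulate → … → communities
brainsync --config my.yaml --outdir out simulate
brainsync --config my.yaml --outdir out compare   # needs simulate outputs
```

Stages: `simulate`, `compare`, `rewire`, `network`, `communities`,
`behavior`, `qc`, `demo`. Each stage writes CSV/JSON artifacts plus a
`manifest.json` (inputs, parameters, stage seed, package version) under
`<outdir>/<stage>/`. Configuration is YAML validated against the default
tree (`brainsync.config.DEFAULTS`); unknown keys are rejected by name. All
randomness derives from the root `seed`, split deterministically per stage.

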