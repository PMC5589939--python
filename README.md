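# brainmux

Multiplex (multi-frequency) brain-network analysis in Python: from band-specific
coherence connectomes to multiplex centrality statistics, permutation group
tests, score correlations, and Mahalanobis classification — plus a synthetic
cohort generator so the whole pipeline is testable without external data.

## What it does

1. **Spectral estimation** (`brainmux.spectral`) — Welch PSD and
   magnitude-squared (or imaginary) coherence between ROI time series,
   averaged into seven canonical frequency bands (delta 2–4 Hz … gamma
   30–45 Hz) and across epochs.
2. **Network construction** (`brainmux.netbuild`) — thresholding weighted
   matrices to a fixed average node degree `k` (exactly `round(k·n/2)`
   strongest edges, deterministic tie-breaking), binarization, multiplex
   assembly with implicit identity inter-layer coupling, and
   overlapping/aggregated flattening.
3. **Single-layer metrics** (`brainmux.graph_metrics`) — seeded randomized
   modularity maximization (igraph multilevel, best-of-restarts) and the
   participation coefficient `PC_i = 1 − Σ_m (k_im/k_i)²`.
4. **Multiplex metrics** (`brainmux.multiplex`) — node-degree layer
   proportion (NLP), multi-participation coefficient
   `MPC_i = M/(M−1)·(1 − Σ_λ NLP²)`, and the across-layer degree CV.
5. **Statistics** (`brainmux.stats`) — permutation t-tests (Z from the
   permutation null, p with the +1 correction), node-wise tests with a shared
   seeded schedule, BH/BY FDR, Spearman correlation with permutation p,
   Kruskal–Wallis with tie correction, and hierarchical global→local gating.
6. **Classification** (`brainmux.classify`) — p-ranked features, a
   Mahalanobis-distance classifier with automatic ridge shrinkage, repeated
   stratified 80/20 cross-validation (classical 5-fold behind a flag),
   ROC/AUC, and the two-family (PC × MPC) feature grid search.
7. **Synthetic cohorts** (`brainmux.synthetic`) — planted-partition weighted
   connectomes with a group-dependent layer imbalance (AD-like concentration
   of degree away from one band), cognitive-like scores coupled to network
   features, and band-coupled signal generation for the spectral stage.
8. **Orchestration** (`brainmux.pipeline`, `brainmux.cli`) — end-to-end runs
   with data-driven threshold selection (first `k` significant in both the
   single-layer and multiplex analysis), config hashing, and reproducible
   JSON summaries.

## CLI

```sh
brainmux simulate --spec spec.json --out cohort/ --seed 3       # synthetic cohort
brainmux connectivity --manifest cohort/manifest.json --out conn/
brainmux build --in conn/HC000 --k 12 --out mx/
brainmux metrics --in mx/ --out metrics/
brainmux stats --features metrics.tsv --labels manifest.json --out stats.tsv
brainmux classify --pc-features pc.tsv --mpc-features mpc.tsv \
    --labels manifest.json --iters 1000 --out clf.json
brainmux pipeline --config cfg.json --manifest cohort/manifest.json --out results/
```

All matrices are dense CSV (6-decimal fixed point), edge lists TSV, manifests
and results JSON; node indexing is 0-based on disk. Every pipeline output
records the config hash and seed for exact re-runs.

### Python example

```python
import numpy as np
from brainmux import (
    CohortSpec, generate_cohort, threshold_to_mean_degree,
    build_multiplex, multi_participation_coefficient,
)

spec = CohortSpec(n_hc=25, n_ad=25, delta=0.5, seed=0)
cohort = generate_cohort(spec)
bc = cohort.connectomes["AD000"]
layers = [threshold_to_mean_degree(m, k=12) for m in bc.matrices]
mpc_per_node, global_mpc = multi_participation_coefficient(build_multiplex(layers))
```

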