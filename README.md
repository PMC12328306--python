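# onidsc

Gene regulatory network inference from pseudotime-ordered single-cell
RNA-seq, built around a lasso Granger-causality model whose penalty is
optimized by cross-validated cyclical coordinate descent rather than fixed
in advance.

## Who this is for

Computational biologists reconstructing directed regulator → target
networks from single-cell expression of a cell population moving through a
biological process (differentiation, immune activation).  The package
covers the full workflow: normalization and gene filtering, supervised
pseudotime from a marker-gene panel, per-gene penalty selection, ensemble
network inference, evaluation against a gold standard of known
interactions, and comparison of networks across patients or cell types.
It also ships a synthetic-data generator with planted regulatory edges so
every stage can be validated end to end without external data.

## The model

Cells are ordered along a pseudotime.  A supervised ordering is used: after
log(x+1) normalization, each cell's pseudotime is the **sum of normalized
marker-gene expression** (for immune activation, the interferon-stimulated
genes), so the order reflects the process of interest rather than global
variance.

For each target gene *y* observed at pseudotimes *t₁ < … < t_N*, every
candidate regulator *x* contributes *L* lagged features built by Gaussian
kernel smoothing over the irregular pseudotime grid,

    x̃_ℓ(tᵢ) = Σ_{t_k < tᵢ} K((t_k − (tᵢ − ℓ·Δt))/σ) · x(t_k) / Σ K(·),

restricted to samples strictly in the target's past.  The target's own
lags enter as covariates, so a regulator is selected only if it predicts
the target beyond the target's autoregression — Granger causality.  The
regression is the lasso,

    min_{β₀,β} (1/2N) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ‖β‖₁,

solved by cyclical coordinate descent, each update a soft-thresholding
step S(z, λ) = sign(z)(|z| − λ)₊.  Instead of running an ensemble over
several fixed penalties, λ is chosen by 10-fold cross-validation per gene
over a shared geometric path; the most frequent per-gene optimum
(`lambda_min`, with `lambda_1se` as the upper end of the optimal range)
gives a single common penalty.

Dropout zeros are mitigated by removing each zero-valued sample with
probability 0.2; technical replicas repeat inference with independent
removal draws.  Each ensemble instance — (Δt, L) pair × kernel width ×
replica — produces an adjacency matrix of summed |β| weights; instance
rankings are combined by a modified Borda count (score = Σ 1/rank), and
predictions are evaluated by precision/recall, average precision, and
early metrics at a partial recall threshold against a closed-world gold
standard.

## Worked example

```python
from onidsc import (SimulationConfig, simulate_network_expression,
                    log1p_normalize, marker_pseudotime, EnsembleSpec,
                    infer_network, precision_recall, average_precision,
                    early_metrics)

cfg = SimulationConfig(n_cells=300, n_genes=10,
                       planted_edges=[(0, 1, 0.9, 1), (2, 3, 0.8, 1)],
                       marker_gene_count=2, noise_sd=0.05, seed=42)
sim = simulate_network_expression(cfg)
Xn = log1p_normalize(sim.matrix)
ordering = marker_pseudotime(Xn, sim.marker_genes).rank_time()
Xi = Xn.subset_genes([g for g in Xn.gene_ids if g not in sim.marker_genes])
spec = EnsembleSpec(lam=0.01, dt_lag_pairs=[(1.0, 2), (2.0, 2)],
                    sigmas=[1.0, 2.0], prob_zero_removal=0.2,
                    replicas=8, seed=42)
edges = infer_network(Xi, ordering, spec)
for reg, tgt, score, rank in edges.records[:5]:
    print(f"  {rank}. {reg} -> {tgt}  score={score:.3f}")
curve = precision_recall(edges, sim.truth, gene_ids=Xi.gene_ids)
ep, er, ea = early_metrics(curve, 0.5)
print(f"average precision = {average_precision(curve):.3f}")
print(f"early precision/recall/accuracy at recall 0.5 = {ep:.3f}/{er:.3f}/{ea:.3f}")
```

prints

```
  1. g007 -> g003  score=16.864
  2. g000 -> g001  score=16.667
  3. g006 -> g000  score=12.742
  4. g003 -> g002  score=8.708
  5. g004 -> g005  score=7.348
average precision = 0.271
early precision/recall/accuracy at recall 0.5 = 0.500/0.500/0.964
```

The stronger planted edge (g000 → g001, coefficient 0.9) ranks second of
72 possible edges; the weaker one (g002 → g003) is missed here because the
marker-derived ordering, though nearly perfect (Spearman ρ ≈ 0.996 against
truth), contains local swaps that disrupt its one-step lag structure —
with the exact ordering both planted edges rank 1–2 and average precision
is 1.0.  Average precision 0.271 compares with a random-network
expectation near the prevalence 2/72 ≈ 0.028.

The same pipeline is available from the shell:

```sh
onidsc simulate --n-cells 300 --n-genes 10 --markers 2 --seed 42 --out-dir data
onidsc preprocess --expression data/matrix.mtx --markers data/markers.txt \
    --rank-time --out-matrix norm.csv --out-pseudotime pt.tsv
onidsc lambda --expression norm.csv --k 10 --seed 42 --out-summary lambda.tsv
onidsc infer --expression norm.csv --pseudotime pt.tsv --lambda 0.01 \
    --replicas 8 --seed 42 --out edges.tsv
onidsc evaluate --edges edges.tsv --gold data/truth.tsv \
    --recall-threshold 0.5 --out metrics.tsv
```

plus `onidsc random-control`, `onidsc compare` (cross-subject shared
relations) and `onidsc run --config pipeline.yaml` for the whole chain.

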